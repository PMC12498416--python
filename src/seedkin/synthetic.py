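"""Synthetic assay data with known ground truth.

Every input the pipeline consumes can be generated here: seeded ThT kinetic
trace families (monomer dilutions, inhibitor dose ladders at low and high
seed), fluorescence-polarization titrations, and a combinatorial screening
library with a hidden structure-activity landscape.  All generators are
fully deterministic under a fixed RNG seed and embed their planted truth in
the returned metadata, so every downstream fitting routine can be checked
against what was planted.

The emulated assay geometry follows the quiescent seeded tau (K12) screen:
5 uM monomer with 50 nM (monomer-equivalent, 1%) preformed seeds, plate
reads every 15 min, monomer dilutions from 3.2 to 15 uM, compound doses at
1x/2x/4x molar equivalents of the 5 uM monomer, high-seed elongation assays
at 2.5 uM seed / 5 uM monomer, and FP titrations of 10 uM compound against
increasing fibril concentrations.  The ThT readout is modelled as linear in
aggregate mass (signal = offset + gain * M(t)) with additive Gaussian
noise; polymorph-specific amplitude differences are represented as distinct
gain parameters only.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .binding import BindingTitration
from .inhibition import DoseSeries
from .kinetics import KineticTrace, RateParameters, simulate_aggregation
from .screening import MoleculeRecord, morgan_fingerprint

from rdkit import Chem, DataStructs

__all__ = [
    "GeneratorConfig",
    "LibrarySpec",
    "default_rate_parameters",
    "gen_dilution_series",
    "gen_inhibitor_doses",
    "gen_fp_titration",
    "gen_library",
    "DILUTION_CONCS_UM",
    "DOSE_LADDER_UM",
]

#: Monomer dilution series (uM), spanning the assayed 3.2-15 uM range.
DILUTION_CONCS_UM = (3.2, 4.0, 6.0, 8.0, 12.0, 15.0)

#: Molar-equivalent dose ladder relative to 5 uM monomer: vehicle, 1x, 2x, 4x.
DOSE_LADDER_UM = (0.0, 5.0, 10.0, 20.0)

#: ThT gain per polymorph (AU per molar of fibril mass): the two fibril
#: folds differ in ThT amplitude, modelled as gain only.
POLYMORPH_GAIN = {"AD": 4.0e8, "PiD": 2.5e8}


@dataclass
class GeneratorConfig:
    """Assay geometry, signal map and noise model shared by all generators."""

    rng_seed: int = 0
    noise_sd_au: float = 20.0          # additive Gaussian noise on the signal
    noise_mult: float = 0.0            # optional multiplicative noise factor
    signal_offset_au: float = 50.0     # ThT baseline a in signal = a + b*M
    signal_gain_au_per_M: float = 4.0e8
    read_interval_s: float = 900.0     # one ThT read every 15 min
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.noise_sd_au < 0 or self.noise_mult < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.read_interval_s <= 0:
            raise ValueError("read interval must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.rng_seed, salt))

    def time_grid(self, duration_s: float) -> np.ndarray:
        n = int(duration_s // self.read_interval_s)
        return np.arange(n + 1) * self.read_interval_s


#: Mean seed length in monomers; sets P_0 = M_0 / seed_length.  Unsonicated
#: quiescently grown fibrils are micron-scale, i.e. of order 1e4 monomers.
DEFAULT_SEED_LENGTH = 1.0e4


def default_rate_parameters(
    monomer_uM: float = 5.0,
    seed_fraction: float = 0.01,
    seed_length: float = DEFAULT_SEED_LENGTH,
    model: str = "fragmentation",
) -> RateParameters:
    """Ground-truth rate constants used by the generators.

    Chosen so the effective self-replication rate kappa = sqrt(2 k+ k- m)
    (or its secondary-nucleation analogue) is ~2.2e-5 s^-1 at 5 uM, placing
    seeded half-times at tens of hours — the timescale of the quiescent
    assays being emulated.  ``fragmentation`` uses fibril breakage as the
    multiplication step; ``saturating`` uses surface-catalysed secondary
    nucleation saturated well below the assay monomer concentrations
    (K_M = 1 uM), so both give the weak ~m^-1/2 half-time scaling.
    """
    m_tot = monomer_uM * 1e-6 / (1.0 - seed_fraction)
    M0 = seed_fraction * m_tot
    base = dict(
        k_plus=5.0e3,             # M^-1 s^-1
        k_n=0.0, n_c=2.0,
        m_tot=m_tot, M_0=M0, P_0=M0 / seed_length,
    )
    if model == "fragmentation":
        return RateParameters(k_minus=1.0e-8, k_2=0.0, **base)
    if model == "saturating":
        return RateParameters(k_minus=0.0, k_2=1.0e4, n_2=2.0, K_M=1.0e-6,
                              **base)
    raise ValueError(f"unknown generator model {model!r}")


def _noisy_signal(trace: KineticTrace, cfg: GeneratorConfig,
                  rng: np.random.Generator, gain: float) -> np.ndarray:
    """Map mass fraction to ThT AU and add the configured noise."""
    m_tot = trace.meta["m_tot"]
    clean = cfg.signal_offset_au + gain * trace.signal * m_tot
    noise = rng.normal(0.0, cfg.noise_sd_au, size=clean.shape)
    if cfg.noise_mult > 0:
        noise = noise + clean * rng.normal(0.0, cfg.noise_mult,
                                           size=clean.shape)
    return clean + noise


# ---------------------------------------------------------------------------
# Kinetic trace families
# ---------------------------------------------------------------------------

def gen_dilution_series(
    config: GeneratorConfig,
    params: RateParameters | None = None,
    monomer_concs_uM: Sequence[float] = DILUTION_CONCS_UM,
    seed_fraction: float = 0.01,
    duration_s: float = 150.0 * 3600.0,
    polymorph: str = "AD",
    as_mass_fraction: bool = False,
) -> list[KineticTrace]:
    """Seeded monomer-dilution trace family with 1% preformed seeds.

    One noisy replicate set per monomer concentration; ``params`` supplies
    the shared rate constants (per-concentration ``m_tot``/``M_0``/``P_0``
    are derived from the dilution).  Ground truth is embedded in each
    trace's metadata.  With ``as_mass_fraction`` the clean normalized curve
    plus scaled noise is returned instead of raw AU (convenient for direct
    global fitting).
    """
    rng = config.rng(salt=1)
    gain = POLYMORPH_GAIN.get(polymorph, config.signal_gain_au_per_M)
    t = config.time_grid(duration_s)
    traces: list[KineticTrace] = []
    for c_uM in monomer_concs_uM:
        if params is None:
            p = default_rate_parameters(c_uM, seed_fraction)
        else:
            m_tot = c_uM * 1e-6 / (1.0 - seed_fraction)
            M0 = seed_fraction * m_tot
            p = params.evolve(m_tot=m_tot, M_0=M0,
                              P_0=M0 * params.P_0 / params.M_0
                              if params.M_0 > 0 else 0.0)
        clean = simulate_aggregation(p, t)
        for rep in range(config.n_replicates):
            meta = {
                "monomer_uM": c_uM, "seed_nM": p.M_0 * 1e9,
                "compound": "none", "compound_uM": 0.0,
                "replicate": rep + 1, "polymorph": polymorph,
                "m_tot": p.m_tot, "M_0": p.M_0, "P_0": p.P_0,
                "truth": {"k_plus": p.k_plus, "k_2": p.k_2,
                          "k_minus": p.k_minus},
            }
            if as_mass_fraction:
                sig = clean.signal + rng.normal(
                    0.0, config.noise_sd_au / (gain * p.m_tot),
                    size=clean.signal.shape)
            else:
                sig = _noisy_signal(clean, config, rng, gain)
            traces.append(KineticTrace(t.copy(), sig, meta))
    return traces


def dose_scaling(dose: float, max_dose: float, d50: float = 5e-6) -> float:
    """Saturating fraction of the maximal effect reached at ``dose``.

    Hyperbolic in dose and normalized to be exactly 1 at ``max_dose``, so a
    planted reduction is realized exactly at the top of the ladder.
    """
    if dose <= 0:
        return 0.0
    return (dose / (dose + d50)) / (max_dose / (max_dose + d50))


def gen_inhibitor_doses(
    config: GeneratorConfig,
    compound_id: str,
    k2_reduction: float = 0.0,
    kplus_reduction: float = 0.0,
    doses_uM: Sequence[float] = DOSE_LADDER_UM,
    model: str = "saturating",
    monomer_uM: float = 5.0,
    low_seed_nM: float = 50.0,
    high_seed_uM: float = 2.5,
    duration_s: float = 150.0 * 3600.0,
    high_seed_duration_s: float = 48.0 * 3600.0,
    d50_uM: float = 5.0,
    as_mass_fraction: bool = False,
) -> tuple[DoseSeries, DoseSeries]:
    """Low-seed and high-seed dose-series trace sets for one compound.

    The planted mechanism is a fractional reduction of k_2 and/or k_plus
    reached exactly at the highest dose, interpolated over the ladder by the
    saturating :func:`dose_scaling` law.  Low-seed reactions (50 nM seeds)
    expose secondary processes; high-seed reactions (2.5 uM seeds) are
    elongation-dominated.  Returns ``(low_seed_series, high_seed_series)``
    with the planted truth in every trace's metadata.
    """
    if not -1.0 <= k2_reduction <= 1.0 or not -1.0 <= kplus_reduction <= 1.0:
        raise ValueError("planted reductions must lie in [-1, 1]")
    rng = config.rng(salt=2)
    gain = config.signal_gain_au_per_M
    max_dose = max(doses_uM)
    base = default_rate_parameters(monomer_uM, model=model)
    # low-seed: scale seed mass to the requested value
    M0_low = low_seed_nM * 1e-9
    m_tot_low = monomer_uM * 1e-6 + M0_low
    base_low = base.evolve(m_tot=m_tot_low, M_0=M0_low,
                           P_0=M0_low / DEFAULT_SEED_LENGTH)
    M0_high = high_seed_uM * 1e-6
    m_tot_high = monomer_uM * 1e-6 + M0_high
    base_high = base.evolve(m_tot=m_tot_high, M_0=M0_high,
                            P_0=M0_high / DEFAULT_SEED_LENGTH)

    def build(series_base: RateParameters, duration: float,
              seed_label: str) -> DoseSeries:
        t = config.time_grid(duration)
        ds = DoseSeries(compound_id=compound_id)
        for dose_uM in doses_uM:
            frac = dose_scaling(dose_uM * 1e-6, max_dose * 1e-6,
                                d50_uM * 1e-6)
            p = series_base.evolve(
                k_2=series_base.k_2 * (1.0 - k2_reduction * frac),
                k_plus=series_base.k_plus * (1.0 - kplus_reduction * frac))
            clean = simulate_aggregation(p, t)
            reps = []
            for rep in range(config.n_replicates):
                meta = {
                    "monomer_uM": monomer_uM,
                    "seed_nM": series_base.M_0 * 1e9,
                    "compound": compound_id if dose_uM > 0 else "DMSO",
                    "compound_uM": dose_uM, "replicate": rep + 1,
                    "seed_regime": seed_label,
                    "m_tot": p.m_tot, "M_0": p.M_0, "P_0": p.P_0,
                    "truth": {
                        "k_2": p.k_2, "k_plus": p.k_plus,
                        "k2_reduction_at_max": k2_reduction,
                        "kplus_reduction_at_max": kplus_reduction,
                        "effect_fraction": frac,
                    },
                }
                if as_mass_fraction:
                    sig = clean.signal + rng.normal(
                        0.0, config.noise_sd_au / (gain * p.m_tot),
                        size=clean.signal.shape)
                else:
                    sig = _noisy_signal(clean, config, rng, gain)
                reps.append(KineticTrace(t.copy(), sig, meta))
            ds.traces[dose_uM * 1e-6] = reps
        return ds

    low = build(base_low, duration_s, "low")
    high = build(base_high, high_seed_duration_s, "high")
    return low, high


# ---------------------------------------------------------------------------
# Fluorescence-polarization titrations
# ---------------------------------------------------------------------------

#: Two-fold fibril dilution ladder (uM, monomer equivalents), top 12.5 uM.
FP_FIBRIL_CONCS_UM = (0.195, 0.39, 0.78, 1.5625, 3.125, 6.25, 12.5)


def gen_fp_titration(
    config: GeneratorConfig,
    compound_id: str,
    K_D: float,
    B_max: float = 60.0,
    fibril_concs: Sequence[float] | None = None,
    noise_sd_mP: float = 2.0,
    ligand_conc: float = 10e-6,
) -> BindingTitration:
    """Hyperbolic one-site FP titration with Gaussian noise.

    Per-level values are means of ``config.n_replicates`` noisy replicates
    with the replicate SD attached; planted K_D (molar) and B_max (mP) are
    the ground truth of the one-site model.
    """
    if K_D <= 0 or B_max <= 0 or noise_sd_mP < 0:
        raise ValueError("K_D and B_max must be positive, noise >= 0")
    rng = config.rng(salt=3)
    F = (np.asarray(fibril_concs, dtype=float) * 1e-6
         if fibril_concs is not None
         else np.asarray(FP_FIBRIL_CONCS_UM) * 1e-6)
    clean = B_max * F / (K_D + F)
    reps = clean[None, :] + rng.normal(
        0.0, noise_sd_mP, size=(config.n_replicates, F.size))
    if config.n_replicates > 1:
        mean, sd = reps.mean(axis=0), reps.std(axis=0, ddof=1)
    else:
        mean, sd = reps[0], np.full(F.size, noise_sd_mP)
    tit = BindingTitration(compound_id=compound_id, fibril_concs=F,
                           delta_mP=mean, sd=sd, ligand_conc=ligand_conc)
    tit.truth = {"K_D": K_D, "B_max": B_max, "noise_sd_mP": noise_sd_mP}
    return tit


# ---------------------------------------------------------------------------
# KIC50 dose-response half-times
# ---------------------------------------------------------------------------

#: Dose ladder (uM) for KIC50-style rate titrations.
KIC50_DOSES_UM = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)


def gen_kic50_series(
    config: GeneratorConfig,
    compound_id: str,
    kic50_uM: float,
    hill: float = 1.5,
    control_half_time_s: float = 5.0e4,
    doses_uM: Sequence[float] = KIC50_DOSES_UM,
    noise_cv: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Half-times whose normalized rate follows a descending logistic.

    The approximate rate 1/t_half, normalized so the vehicle is 100, follows
    ``100 / (1 + (d / KIC50)^hill)``; half-times carry multiplicative
    log-normal noise of coefficient of variation ``noise_cv``.  Returns
    ``(doses_M, half_times_s, control_half_time_s)``.
    """
    if kic50_uM <= 0:
        raise ValueError("planted KIC50 must be positive")
    rng = config.rng(salt=4)
    d = np.asarray(doses_uM, dtype=float)
    rate = 100.0 / (1.0 + (d / kic50_uM) ** hill)
    th = control_half_time_s * 100.0 / rate
    th = th * np.exp(rng.normal(0.0, noise_cv, size=th.shape))
    return d * 1e-6, th, float(control_half_time_s)


# ---------------------------------------------------------------------------
# Screening library with a hidden structure-activity landscape
# ---------------------------------------------------------------------------

# Two-slot scaffolds; the first two carry the oxadiazole motif recurrent in
# the active chemotype.
_SCAFFOLDS = (
    "c1ccc({a})cc1-c1nnc({b})o1",          # phenyl-1,3,4-oxadiazole
    "c1ccc({a})cc1-c1noc({b})n1",          # phenyl-1,2,4-oxadiazole
    "c1ccc({a})cc1C(=O)Nc1ccc({b})cc1",    # benzanilide
    "c1cc({a})ccc1-c1nc2cc({b})ccc2o1",    # 2-arylbenzoxazole
    "c1cc({a})ccc1-c1nc2cc({b})ccc2[nH]1", # 2-arylbenzimidazole
    "c1nc({a})nc({b})n1",                  # 1,3,5-triazine
    "c1cc({a})ccc1S(=O)(=O)Nc1ccc({b})cc1",# sulfonanilide
    "c1cc({a})ccc1-c1cc({b})on1",          # arylisoxazole
    "c1cc({a})ccc1/C=C/c1ccc({b})cc1",     # stilbene
    "c1cc({a})ccc1Oc1ccc({b})cc1",         # diaryl ether
)

_SUBSTITUENTS = (
    "[H]", "C", "CC", "O", "OC", "F", "Cl", "C#N", "C(F)(F)F",
    "N", "N(C)C", "CO", "C(C)C", "OCC", "C(=O)N", "c2ccccc2",
)


@dataclass
class LibrarySpec:
    """Size and hidden-activity landscape of the synthetic library."""

    size: int = 2000
    n_actives: int = 8
    kernel_width: float = 0.30     # Tanimoto-distance width of the activity bump
    max_ratio: float = 3.0         # planted normalized t1/2 at an active
    noise_sd: float = 0.10         # assay noise on the oracle ratio
    active_scaffolds: tuple[int, ...] = (0, 1)  # oxadiazole family

    def __post_init__(self) -> None:
        if self.size < 10 or self.n_actives < 1:
            raise ValueError("library too small")
        if self.kernel_width <= 0 or self.max_ratio <= 1:
            raise ValueError("kernel width must be > 0 and max_ratio > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _enumerate_library() -> list[str]:
    """All valid, canonical, unique scaffold-substituent combinations."""
    seen: set[str] = set()
    out: list[str] = []
    for scaf in _SCAFFOLDS:
        for a in _SUBSTITUENTS:
            for b in _SUBSTITUENTS:
                smi = scaf.format(a=a, b=b)
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    continue
                can = Chem.MolToSmiles(mol)
                if can not in seen:
                    seen.add(can)
                    out.append(can)
    return out


def _stable_hash(text: str) -> int:
    return int.from_bytes(
        hashlib.blake2b(text.encode(), digest_size=8).digest(), "big")


def gen_library(
    config: GeneratorConfig,
    spec: LibrarySpec | None = None,
) -> tuple[list[MoleculeRecord], Callable[[MoleculeRecord | str], float],
           dict]:
    """Synthetic screening library plus its measurement oracle.

    The library enumerates a scaffold-substituent grammar (including an
    oxadiazole-bearing family), canonicalizes and de-duplicates, and samples
    ``spec.size`` members deterministically.  ``spec.n_actives`` hidden
    actives are drawn from the oxadiazole scaffolds; the oracle returns

        t12_norm = 1 + (max_ratio - 1) * exp(-d^2 / w^2) + noise

    where ``d`` is the Tanimoto distance of the molecule's fingerprint to
    its nearest hidden active.  Oracle noise is derived from a stable hash
    of the canonical SMILES and the seed, so it is identical across calls
    and invariant under SMILES rewriting.  Returns
    ``(records, oracle, truth)`` with the planted actives listed in truth.
    """
    spec = spec or LibrarySpec()
    rng = config.rng(salt=5)
    all_smiles = _enumerate_library()
    if spec.size > len(all_smiles):
        raise ValueError(
            f"library grammar yields only {len(all_smiles)} molecules")
    idx = rng.permutation(len(all_smiles))[: spec.size]
    smiles = [all_smiles[i] for i in sorted(idx)]
    records = [MoleculeRecord(id=f"M{i:05d}", smiles=s)
               for i, s in enumerate(smiles)]

    # hidden actives from the oxadiazole family
    family_markers = [
        Chem.MolToSmiles(Chem.MolFromSmiles(_SCAFFOLDS[j].format(a="[H]",
                                                                 b="[H]")))
        for j in spec.active_scaffolds]
    family_patts = [Chem.MolFromSmarts(
        Chem.MolToSmarts(Chem.MolFromSmiles(m))) for m in family_markers]
    family_ids = [r.id for r in records
                  if any(Chem.MolFromSmiles(r.smiles).HasSubstructMatch(p)
                         for p in family_patts)]
    if len(family_ids) < spec.n_actives:
        family_ids = [r.id for r in records]
    active_ids = sorted(rng.choice(family_ids, size=spec.n_actives,
                                   replace=False))
    by_id = {r.id: r for r in records}
    active_fps = [morgan_fingerprint(by_id[a].smiles) for a in active_ids]

    def oracle(mol: MoleculeRecord | str) -> float:
        smi = mol.smiles if isinstance(mol, MoleculeRecord) else mol
        can = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
        fp = morgan_fingerprint(can)
        sims = [DataStructs.TanimotoSimilarity(fp, a) for a in active_fps]
        d = 1.0 - max(sims)
        bump = (spec.max_ratio - 1.0) * math.exp(-(d / spec.kernel_width) ** 2)
        noise_rng = np.random.default_rng(
            (_stable_hash(can) % (2 ** 31), config.rng_seed))
        return 1.0 + bump + float(noise_rng.normal(0.0, spec.noise_sd))

    truth = {
        "active_ids": list(active_ids),
        "active_smiles": [by_id[a].smiles for a in active_ids],
        "kernel_width": spec.kernel_width,
        "max_ratio": spec.max_ratio,
        "noise_sd": spec.noise_sd,
        "library_size": len(records),
        "rng_seed": config.rng_seed,
    }
    return records, oracle, truth
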