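"""Active-learning optimization of aggregation inhibitors.

The screening loop alternates between measuring a batch of compounds in the
seeded-aggregation assay and retraining a surrogate that predicts the
normalized half-time from molecular structure.  The surrogate is two-stage:
a random forest captures the bulk structure-activity signal and a Gaussian
process is fitted to the forest's residuals, supplying a smooth correction
and, crucially, a predictive uncertainty.  Candidates are ranked by an
upper-confidence-bound acquisition ``mean + beta * sd``; ``beta`` tunes the
exploration/exploitation balance.

Molecules are featurized with hashed circular (Morgan) fingerprints by
default; the featurizer is a plain function of SMILES so learned embeddings
can be substituted.  Chemotype grouping uses leader-style (Butina)
clustering on fingerprint Tanimoto similarity, and library pre-filtering
uses the six-component CNS multiparameter-optimization desirability score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator
from rdkit.ML.Cluster import Butina

from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .inhibition import classify_hit

__all__ = [
    "MoleculeRecord",
    "CampaignState",
    "TwoStageSurrogate",
    "FeaturizationError",
    "featurize",
    "morgan_fingerprint",
    "tanimoto_similarity",
    "train_surrogate",
    "acquisition_score",
    "select_batch",
    "run_campaign",
    "tanimoto_cluster",
    "cns_mpo_score",
    "cns_mpo_filter",
]


class FeaturizationError(ValueError):
    """SMILES could not be parsed/featurized."""


@dataclass
class MoleculeRecord:
    """One library member: identifier, structure, and screen bookkeeping."""

    id: str
    smiles: str
    features: np.ndarray | None = None
    measured_t12_norm: float | None = None
    iteration_tested: int | None = None


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

_FP_GEN_CACHE: dict[tuple[int, int], object] = {}


def _fp_generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _FP_GEN_CACHE:
        _FP_GEN_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits)
    return _FP_GEN_CACHE[key]


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    return mol


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048):
    """Binary Morgan fingerprint as an RDKit ExplicitBitVect."""
    return _fp_generator(radius, n_bits).GetFingerprint(_mol_from_smiles(smiles))


def featurize(smiles: str, radius: int = 2, n_bits: int = 2048,
              descriptors: bool = False) -> np.ndarray:
    """Deterministic fixed-length feature vector for one molecule.

    Hashed circular fingerprint bits (0/1), optionally extended with a small
    block of physicochemical descriptors.  Invariant under SMILES
    re-canonicalization because featurization goes through the parsed
    molecular graph.
    """
    mol = _mol_from_smiles(smiles)
    fp = _fp_generator(radius, n_bits).GetFingerprint(mol)
    vec = np.zeros(n_bits, dtype=np.float64)
    DataStructs.ConvertToNumpyArray(fp, vec)
    if descriptors:
        desc = np.array([
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            Descriptors.TPSA(mol),
            Lipinski.NumHDonors(mol),
            Lipinski.NumHAcceptors(mol),
            Descriptors.NumRotatableBonds(mol),
        ])
        vec = np.concatenate([vec, desc])
    return vec


def tanimoto_similarity(smiles_a: str, smiles_b: str,
                        radius: int = 2, n_bits: int = 2048) -> float:
    """Tanimoto similarity of binary Morgan fingerprints."""
    fa = morgan_fingerprint(smiles_a, radius, n_bits)
    fb = morgan_fingerprint(smiles_b, radius, n_bits)
    return float(DataStructs.TanimotoSimilarity(fa, fb))


# ---------------------------------------------------------------------------
# Two-stage surrogate
# ---------------------------------------------------------------------------

class TwoStageSurrogate:
    """Random-forest mean with a Gaussian-process residual correction.

    Stage 1 regresses the normalized half-time on the features with a random
    forest; stage 2 fits a GP (RBF + white-noise kernel, hyperparameters by
    marginal likelihood) to the forest's training residuals.  The prediction
    is RF mean plus GP residual mean; the predictive SD comes from the GP.
    """

    def __init__(self, n_trees: int = 500, random_state: int = 0,
                 gp_length_scale: float = 10.0):
        self.n_trees = n_trees
        self.random_state = random_state
        self.gp_length_scale = gp_length_scale
        self.rf: RandomForestRegressor | None = None
        self.gp: GaussianProcessRegressor | None = None
        self.degenerate = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TwoStageSurrogate":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(y) < 8:
            raise ValueError("need at least 8 labelled molecules")
        kernel = (ConstantKernel(1.0, (1e-4, 1e4))
                  * RBF(self.gp_length_scale, (1e-2, 1e4))
                  + WhiteKernel(1e-2, (1e-10, 1e2)))
        self.gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=False, n_restarts_optimizer=2,
            random_state=self.random_state)
        if np.ptp(y) == 0.0:
            # constant targets: the forest is uninformative, keep the GP so
            # uncertainties still rank candidates by novelty
            warnings.warn("constant targets: uncertainty-only surrogate",
                          stacklevel=2)
            self.degenerate = True
            self.rf = None
            self.gp.fit(X, np.zeros_like(y))
            self._const = float(y[0])
            return self
        self.rf = RandomForestRegressor(
            n_estimators=self.n_trees, random_state=self.random_state,
            n_jobs=1)
        self.rf.fit(X, y)
        resid = y - self.rf.predict(X)
        self.gp.fit(X, resid)
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (predictive mean, predictive SD) for each row of X."""
        X = np.asarray(X, dtype=float)
        resid_mean, sd = self.gp.predict(X, return_std=True)
        if self.degenerate:
            return np.full(len(X), self._const) + resid_mean, sd
        return self.rf.predict(X) + resid_mean, sd


def train_surrogate(features: np.ndarray, targets: Sequence[float],
                    random_state: int = 0, n_trees: int = 500) -> TwoStageSurrogate:
    """Fit the two-stage surrogate on labelled molecules."""
    return TwoStageSurrogate(n_trees=n_trees, random_state=random_state).fit(
        np.asarray(features, dtype=float), np.asarray(targets, dtype=float))


def acquisition_score(pred_mean, pred_sd, beta: float = 1.0):
    """Upper-confidence-bound acquisition: ``mean + beta * sd``.

    ``beta = 0`` is pure exploitation (rank by predicted potency); larger
    ``beta`` weights the GP uncertainty, pushing the selection toward
    unexplored chemical space.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    mean = np.asarray(pred_mean, dtype=float)
    sd = np.asarray(pred_sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("predictive SD must be non-negative")
    return mean + beta * sd


# ---------------------------------------------------------------------------
# Campaign loop
# ---------------------------------------------------------------------------

@dataclass
class CampaignState:
    """Library, measurements and per-iteration bookkeeping of one campaign."""

    library: list[MoleculeRecord]
    beta: float = 1.0
    surrogate: TwoStageSurrogate | None = None
    history: list[dict] = field(default_factory=list)
    rng_seed: int | None = None

    @property
    def tested(self) -> list[MoleculeRecord]:
        return [m for m in self.library if m.measured_t12_norm is not None]

    @property
    def untested(self) -> list[MoleculeRecord]:
        return [m for m in self.library if m.measured_t12_norm is None]

    def record_iteration(self, iteration: int, batch: list[MoleculeRecord]):
        classes = [classify_hit(m.measured_t12_norm) for m in batch]
        n_potent = sum(c == "potent" for c in classes)
        n_high = sum(c == "highly_potent" for c in classes)
        self.history.append({
            "iteration": iteration,
            "n_tested": len(batch),
            "n_potent": n_potent,
            "n_highly_potent": n_high,
            "hit_rate": (n_potent + n_high) / len(batch) if batch else 0.0,
        })


def select_batch(
    state: CampaignState,
    batch_size: int,
    scores: dict[str, float],
    diversity_cutoff: float | None = None,
) -> list[str]:
    """Top-scoring untested molecule ids, optionally diversity-filtered.

    Ties are broken by lexicographic molecule id so selection is
    deterministic.  With a diversity cutoff, a candidate is skipped if its
    Tanimoto similarity to an already-selected batch member exceeds the
    cutoff (cutoff 1.0 therefore reduces to pure greedy top-k).
    """
    pool = state.untested
    if len(pool) < batch_size:
        raise ValueError(
            f"untested pool ({len(pool)}) smaller than batch ({batch_size})")
    ranked = sorted(pool, key=lambda m: (-scores[m.id], m.id))
    if diversity_cutoff is None or diversity_cutoff >= 1.0:
        return [m.id for m in ranked[:batch_size]]
    chosen: list[MoleculeRecord] = []
    chosen_fps = []
    deferred: list[MoleculeRecord] = []
    for mol in ranked:
        if len(chosen) == batch_size:
            break
        fp = morgan_fingerprint(mol.smiles)
        if any(DataStructs.TanimotoSimilarity(fp, f) > diversity_cutoff
               for f in chosen_fps):
            deferred.append(mol)
            continue
        chosen.append(mol)
        chosen_fps.append(fp)
    for mol in deferred:  # backfill if the filter was too strict
        if len(chosen) == batch_size:
            break
        chosen.append(mol)
    return [m.id for m in chosen]


def run_campaign(
    library: Iterable[MoleculeRecord],
    oracle: Callable[[MoleculeRecord], float],
    batch_sizes: Sequence[int],
    beta: float = 1.0,
    rng_seed: int = 0,
    initial_ids: Sequence[str] | None = None,
    initial_size: int = 105,
    diversity_cutoff: float | None = None,
    n_trees: int = 500,
    featurizer: Callable[[str], np.ndarray] = featurize,
) -> CampaignState:
    """Run the full measure-train-score-select loop.

    The campaign seeds with an initial batch (a user-supplied id list, e.g.
    docking hits, or a uniform random draw of ``initial_size``), then for
    each entry of ``batch_sizes`` retrains the surrogate on everything
    measured so far, scores the untested pool with the UCB acquisition and
    measures the selected batch with ``oracle``.  History records the potent
    / highly-potent counts and hit rate of every iteration (iteration 0 is
    the initial batch).  Identical seeds and configuration give bit-identical
    selections and history.
    """
    lib = [MoleculeRecord(m.id, m.smiles, m.features) for m in library]
    if len({m.id for m in lib}) != len(lib):
        raise ValueError("duplicate molecule ids in library")
    state = CampaignState(library=lib, beta=beta, rng_seed=rng_seed)
    by_id = {m.id: m for m in lib}
    rng = np.random.default_rng(rng_seed)

    for m in lib:
        if m.features is None:
            m.features = featurizer(m.smiles)

    def measure(ids: Sequence[str], iteration: int) -> list[MoleculeRecord]:
        batch = []
        for mid in ids:
            mol = by_id[mid]
            if mol.measured_t12_norm is not None:
                raise ValueError(f"molecule {mid} selected twice")
            mol.measured_t12_norm = float(oracle(mol))
            mol.iteration_tested = iteration
            batch.append(mol)
        return batch

    if initial_ids is not None:
        first = list(initial_ids)
    else:
        k = min(initial_size, len(lib))
        first = [m.id for m in sorted(lib, key=lambda m: m.id)]
        first = list(rng.choice(first, size=k, replace=False))
    state.record_iteration(0, measure(first, 0))

    for it, size in enumerate(batch_sizes, start=1):
        tested = state.tested
        X = np.stack([m.features for m in tested])
        y = np.array([m.measured_t12_norm for m in tested])
        state.surrogate = train_surrogate(X, y, random_state=rng_seed,
                                          n_trees=n_trees)
        pool = state.untested
        if not pool:
            break
        Xp = np.stack([m.features for m in pool])
        mean, sd = state.surrogate.predict(Xp)
        scores = dict(zip((m.id for m in pool),
                          acquisition_score(mean, sd, beta)))
        size = min(size, len(pool))
        ids = select_batch(state, size, scores,
                           diversity_cutoff=diversity_cutoff)
        state.record_iteration(it, measure(ids, it))
    return state


# ---------------------------------------------------------------------------
# Tanimoto (Butina) clustering
# ---------------------------------------------------------------------------

def tanimoto_cluster(
    smiles: Sequence[str],
    cutoff: float = 0.78,
    radius: int = 2,
    n_bits: int = 2048,
) -> list[list[int]]:
    """Leader-style clustering on fingerprint Tanimoto similarity.

    Returns clusters as lists of indices into ``smiles``; the first index of
    each cluster is the centroid, and every member has Tanimoto similarity
    >= ``cutoff`` to its centroid.  Centroids are the natural candidates for
    a purchase list (one representative per chemotype).
    """
    smiles = list(smiles)
    if not smiles:
        raise ValueError("empty molecule list")
    fps = [morgan_fingerprint(s, radius, n_bits) for s in smiles]
    n = len(fps)
    dists = []
    for i in range(1, n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        dists.extend(1.0 - s for s in sims)
    raw = Butina.ClusterData(dists, n, 1.0 - cutoff, isDistData=True)
    return [list(cluster) for cluster in raw]


# ---------------------------------------------------------------------------
# CNS MPO desirability filter
# ---------------------------------------------------------------------------

def _desirability_mono(value: float, ideal_max: float, zero_at: float) -> float:
    """1 below ideal_max, 0 above zero_at, linear in between."""
    if value <= ideal_max:
        return 1.0
    if value >= zero_at:
        return 0.0
    return (zero_at - value) / (zero_at - ideal_max)


def _desirability_hump(value: float, lo0: float, lo1: float,
                       hi1: float, hi0: float) -> float:
    """0 outside [lo0, hi0], 1 inside [lo1, hi1], linear ramps between."""
    if value <= lo0 or value >= hi0:
        return 0.0
    if lo1 <= value <= hi1:
        return 1.0
    if value < lo1:
        return (value - lo0) / (lo1 - lo0)
    return (hi0 - value) / (hi0 - hi1)


def _basic_pka_proxy(mol: Chem.Mol) -> float:
    """Crude most-basic-centre pKa estimate from substructure classes.

    Aliphatic amines ~10, amidines/guanidines higher, anilines/azines weakly
    basic, everything else treated as non-basic (pKa below the scoring
    window).  Declared as a proxy in the output metadata; a real pKa
    predictor can be substituted.
    """
    patterns = [
        ("[NX3;H2;!$(NC=O);!$(Na)]", 9.5),   # primary aliphatic amine
        ("[NX3;H1;!$(NC=O);!a]", 10.0),      # secondary aliphatic amine
        ("[NX3;H0;!$(NC=O);!a;!$(N=*)]", 9.8),
        ("NC(=N)N", 12.5),                   # guanidine
        ("[nX2]1ccccc1", 5.2),               # pyridine-like
        ("c[NX3;H2]", 4.6),                  # aniline
    ]
    best = 0.0
    for smarts, pka in patterns:
        patt = Chem.MolFromSmarts(smarts)
        if patt is not None and mol.HasSubstructMatch(patt):
            best = max(best, pka)
    return best


def cns_mpo_score(smiles: str) -> tuple[float, dict[str, float]]:
    """Six-component CNS multiparameter-optimization desirability score.

    Components (each in [0, 1], summed to a score in [0, 6]): calculated
    logP (ideal <= 3, zero >= 5), a logD proxy (calculated logP reused,
    ideal <= 2, zero >= 4), molecular weight (ideal <= 360 Da, zero >= 500),
    TPSA (ideal 40-90 A^2, zero outside 20-120), H-bond donors (ideal
    <= 0.5, zero >= 3.5) and the most-basic-centre pKa proxy (ideal <= 8,
    zero >= 10).
    """
    mol = _mol_from_smiles(smiles)
    clogp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    tpsa = Descriptors.TPSA(mol)
    hbd = Lipinski.NumHDonors(mol)
    pka = _basic_pka_proxy(mol)
    components = {
        "clogP": _desirability_mono(clogp, 3.0, 5.0),
        "clogD": _desirability_mono(clogp, 2.0, 4.0),  # clogP as logD proxy
        "MW": _desirability_mono(mw, 360.0, 500.0),
        "TPSA": _desirability_hump(tpsa, 20.0, 40.0, 90.0, 120.0),
        "HBD": _desirability_mono(float(hbd), 0.5, 3.5),
        "pKa": _desirability_mono(pka, 8.0, 10.0),
    }
    return float(sum(components.values())), components


def cns_mpo_filter(
    molecules: Iterable[MoleculeRecord],
    threshold: float = 4.0,
) -> tuple[list[MoleculeRecord], dict[str, float], list[tuple[str, str]]]:
    """Keep molecules with CNS MPO score >= threshold.

    Returns ``(passing, scores_by_id, rejected)`` where ``rejected`` pairs a
    molecule id with the reason (descriptor failure or sub-threshold score
    are both recorded; only descriptor failures are excluded from
    ``scores_by_id``).
    """
    passing, scores, rejected = [], {}, []
    for mol in molecules:
        try:
            score, _ = cns_mpo_score(mol.smiles)
        except FeaturizationError as exc:
            rejected.append((mol.id, f"descriptor failure: {exc}"))
            continue
        scores[mol.id] = score
        if score >= threshold:
            passing.append(mol)
        else:
            rejected.append((mol.id, f"score {score:.2f} < {threshold:g}"))
    return passing, scores, rejected
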