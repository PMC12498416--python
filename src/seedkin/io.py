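"""File readers/writers, run manifests and summary reports.

All delimited files are comma-separated UTF-8 with ``#``-prefixed comment
lines permitted.  Column names carry explicit units (``_s``, ``_uM``,
``_mP``); files store time in seconds and concentrations in micromolar
while the library works in SI internally.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .binding import BindingTitration
from .kinetics import KineticTrace

__all__ = [
    "PLATE_COLUMNS",
    "PlateTableError",
    "RunManifest",
    "read_plate_table",
    "write_plate_table",
    "read_titration_table",
    "write_titration_table",
    "read_smiles_library",
    "write_smiles_library",
    "report",
]

PLATE_COLUMNS = ["well", "condition", "monomer_uM", "seed_nM", "compound",
                 "compound_uM", "replicate", "time_s", "fluorescence"]


class PlateTableError(ValueError):
    """Malformed plate-reader table (message carries row numbers)."""


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Plate-reader long tables
# ---------------------------------------------------------------------------

def read_plate_table(path) -> list[KineticTrace]:
    """Read a long-format plate table into per-well kinetic traces.

    Rows are grouped by well, sorted by time; condition labels land in each
    trace's ``meta``.  Missing columns and duplicate ``(well, time_s)`` rows
    raise :class:`PlateTableError` with row numbers.
    """
    df = _read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateTableError(f"missing required columns: {missing}")
    if df.empty:
        return []
    dup = df.duplicated(subset=["well", "time_s"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based incl. header
        raise PlateTableError(f"duplicate (well, time_s) rows at lines {rows}")
    traces = []
    for well, g in df.groupby("well", sort=True):
        g = g.sort_values("time_s")
        first = g.iloc[0]
        meta = {
            "well": well,
            "condition": first["condition"],
            "monomer_uM": float(first["monomer_uM"]),
            "seed_nM": float(first["seed_nM"]),
            "compound": first["compound"],
            "compound_uM": float(first["compound_uM"]),
            "replicate": int(first["replicate"]),
        }
        traces.append(KineticTrace(g["time_s"].to_numpy(dtype=float),
                                   g["fluorescence"].to_numpy(dtype=float),
                                   meta))
    return traces


def write_plate_table(traces: Iterable[KineticTrace], path) -> None:
    """Write traces in the long plate-table dialect (round-trips with
    :func:`read_plate_table`)."""
    rows = []
    for i, tr in enumerate(traces):
        meta = tr.meta
        well = meta.get("well", f"W{i + 1:03d}")
        for t, y in zip(tr.time, tr.signal):
            rows.append({
                "well": well,
                "condition": meta.get("condition", ""),
                "monomer_uM": meta.get("monomer_uM", np.nan),
                "seed_nM": meta.get("seed_nM", np.nan),
                "compound": meta.get("compound", ""),
                "compound_uM": meta.get("compound_uM", 0.0),
                "replicate": meta.get("replicate", 1),
                "time_s": t,
                "fluorescence": y,
            })
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FP titration tables
# ---------------------------------------------------------------------------

def read_titration_table(path) -> list[BindingTitration]:
    """Read ``compound,fibril_uM,delta_mP,sd`` rows into titrations."""
    df = _read_csv(path)
    needed = ["compound", "fibril_uM", "delta_mP"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise PlateTableError(f"missing required columns: {missing}")
    out = []
    for cid, g in df.groupby("compound", sort=True):
        g = g.sort_values("fibril_uM")
        sd = g["sd"].to_numpy(dtype=float) if "sd" in g.columns else None
        out.append(BindingTitration(
            compound_id=str(cid),
            fibril_concs=g["fibril_uM"].to_numpy(dtype=float) * 1e-6,
            delta_mP=g["delta_mP"].to_numpy(dtype=float),
            sd=sd))
    return out


def write_titration_table(titrations: Iterable[BindingTitration], path) -> None:
    rows = []
    for tit in titrations:
        for i, (f, y) in enumerate(zip(tit.fibril_concs, tit.delta_mP)):
            rows.append({
                "compound": tit.compound_id,
                "fibril_uM": f * 1e6,
                "delta_mP": y,
                "sd": tit.sd[i] if tit.sd is not None else np.nan,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SMILES libraries
# ---------------------------------------------------------------------------

def read_smiles_library(path) -> list[tuple[str, str]]:
    """Read ``id<TAB>smiles`` (or id,smiles CSV) into (id, smiles) pairs."""
    path = Path(path)
    text = path.read_text()
    pairs = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        if len(parts) < 2:
            raise PlateTableError(f"line {ln}: expected 'id<TAB>smiles'")
        if ln == 1 and parts[1].strip().lower() == "smiles":
            continue  # header
        pairs.append((parts[0].strip(), parts[1].strip()))
    return pairs


def write_smiles_library(pairs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for mid, smi in pairs:
            fh.write(f"{mid}\t{smi}\n")


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run one pipeline invocation bit-identically."""

    command: str
    config: dict = field(default_factory=dict)
    rng_seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)      # path -> sha256
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    started: float = field(default_factory=_time.time)
    timings_s: dict = field(default_factory=dict)

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _digest(path)

    def finish(self, stage: str = "total") -> None:
        self.timings_s[stage] = _time.time() - self.started

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "command": self.command,
                "version": self.version,
                "config": self.config,
                "rng_seeds": self.rng_seeds,
                "inputs": self.inputs,
                "outputs": self.outputs,
                "timings_s": self.timings_s,
            }, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Summary report
# ---------------------------------------------------------------------------

def report(
    campaign_history: Sequence[Mapping] | None = None,
    compound_table: pd.DataFrame | None = None,
    mechanisms: Sequence[Mapping] | None = None,
    bindings: Sequence[Mapping] | None = None,
    kic50s: Mapping[str, Mapping] | None = None,
    top_n: int = 10,
) -> tuple[dict, str]:
    """Assemble machine- and human-readable run summaries.

    ``compound_table`` is the screen summary (columns including ``compound``
    and ``t12_norm``); the report lists per-iteration hit rates and the top
    compounds by normalized half-time, plus any mechanism, binding and
    KIC50 results supplied.  Missing sections are reported as explicit
    gaps rather than omitted silently.
    """
    doc: dict = {"sections": []}
    lines: list[str] = ["seedkin run summary", "=" * 19]

    if campaign_history is not None:
        hist = [dict(h) for h in campaign_history]
        doc["campaign"] = {"n_iterations": len(hist), "history": hist}
        doc["sections"].append("campaign")
        lines.append("\nPer-iteration hit rates")
        lines.append(f"{'iter':>4} {'tested':>7} {'potent':>7} "
                     f"{'high':>5} {'hit rate':>9}")
        for h in hist:
            lines.append(f"{h['iteration']:>4} {h['n_tested']:>7} "
                         f"{h['n_potent']:>7} {h['n_highly_potent']:>5} "
                         f"{h['hit_rate']:>8.1%}")
        if not hist:
            lines.append("  (no iterations)")
    else:
        doc["campaign"] = None
        lines.append("\n[campaign results not provided]")

    if compound_table is not None and not compound_table.empty:
        top = compound_table.sort_values(
            "t12_norm", ascending=False).head(top_n)
        doc["top_compounds"] = top.to_dict(orient="records")
        doc["sections"].append("top_compounds")
        lines.append(f"\nTop {min(top_n, len(compound_table))} compounds "
                     "by normalized t1/2")
        for _, row in top.iterrows():
            lines.append(f"  {row['compound']:<12} t1/2 norm = "
                         f"{row['t12_norm']:.2f}")
    else:
        doc["top_compounds"] = None
        lines.append("\n[screen summary table not provided]")

    for key, payload in (("mechanisms", mechanisms), ("bindings", bindings),
                         ("kic50", kic50s)):
        if payload:
            doc[key] = (list(payload) if not isinstance(payload, Mapping)
                        else dict(payload))
            doc["sections"].append(key)
        else:
            doc[key] = None
            lines.append(f"[{key} results not provided]")
    if mechanisms:
        lines.append("\nMechanism (fractional rate-constant reductions at "
                     "top dose)")
        for m in mechanisms:
            dk2 = m.get("delta_k2")
            dkp = m.get("delta_kplus")
            lines.append(
                f"  {m.get('compound', '?'):<12} "
                f"k2: {dk2 * 100:.0f}%  " if dk2 is not None else
                f"  {m.get('compound', '?'):<12} k2: n/a  ")
            if dkp is not None:
                lines[-1] += f"k+: {dkp * 100:.0f}%"
    if bindings:
        lines.append("\nBinding (one-site fit)")
        for b in bindings:
            kd = b.get("K_D_M")
            lines.append(f"  {b.get('compound', '?'):<12} "
                         f"K_D = {kd * 1e6:.2f} uM"
                         + ("  [poorly determined]"
                            if b.get("poorly_determined") else ""))
    if kic50s:
        lines.append("\nKIC50")
        for cid, k in kic50s.items():
            v = k.get("value_M")
            lines.append(f"  {cid:<12} KIC50 = "
                         + (f"{v * 1e6:.2f} uM" if v is not None
                            else f"> {k.get('bound_M', 0) * 1e6:.0f} uM"))

    return doc, "\n".join(lines) + "\n"
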