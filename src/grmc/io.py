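"""Readers/writers for FISH tables, Hi-C count tables, and loop-anchor lists.

Dialects
--------
FISH raw distances:  CSV/TSV with columns ``pair_id, distance_um``
                     (one row per cell).
FISH CDF curves:     CSV/TSV with columns ``pair_id, r_um, cdf``.
Hi-C counts:         CSV/TSV with columns ``pair_id, contact_count``.
Loops:               BEDPE (chrom1 start1 end1 chrom2 start2 end2, 0-based
                     half-open) mapped to monomer indices by
                     ``floor(start / bin_size)`` with 1200 bp per monomer by
                     default, or a plain two-column index CSV.

The :func:`pipeline_reconcile` driver ties the pieces together: per-pair
mixture fits of the FISH curves, predicted contact probabilities at the
configured threshold, and a relative-contact-frequency comparison against the
Hi-C counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .mixture import (
    FISHDataset,
    compare_to_hic,
    fit_mixture,
    mixture_contact_prob,
    relative_contact_frequencies,
)

logger = logging.getLogger("grmc")

__all__ = [
    "RunConfig",
    "read_fish",
    "write_fish",
    "read_hic_counts",
    "read_bedpe",
    "read_loop_indices",
    "write_results",
    "save_trajectory",
    "load_trajectory",
    "pipeline_reconcile",
]

DEFAULT_BIN_SIZE = 1200  # bp per monomer


@dataclass
class RunConfig:
    """Per-run configuration and provenance."""

    units: str = "um"
    r_c: float = 0.010  # 10 nm in micrometers, the default for real-data contact prediction
    family: str = "rdc"
    g: float = 1.0
    delta: float = 1.25
    alpha: float = 1e-2
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self):
        if self.units not in ("um", "a"):
            raise ValueError("units must be 'um' (micrometers) or 'a' (bond lengths)")
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")

    def provenance(self) -> dict:
        from . import __version__

        rec = asdict(self)
        rec["version"] = __version__
        return rec


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty input file")
    sep = "\t" if path.suffix.lower() in (".tsv", ".bed", ".bedpe") else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def _require_columns(df: pd.DataFrame, path, *alternatives):
    for cols in alternatives:
        if all(c in df.columns for c in cols):
            return cols
    raise ValueError(
        f"{path}: expected columns {' or '.join(str(list(c)) for c in alternatives)}, "
        f"found {list(df.columns)}"
    )


def read_fish(path) -> dict[str, FISHDataset]:
    """Read a FISH table into per-pair datasets (raw distances or CDF curves)."""
    df = _read_table(path)
    cols = _require_columns(df, path, ("pair_id", "distance_um"), ("pair_id", "r_um", "cdf"))
    raw = "distance_um" in cols
    value_cols = [c for c in cols if c != "pair_id"]
    bad = df.index[df[value_cols].isna().any(axis=1) | df["pair_id"].isna()]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    out = {}
    for pair_id, grp in df.groupby("pair_id", sort=False):
        if raw:
            if (grp["distance_um"] < 0).any():
                line = int(grp.index[grp["distance_um"] < 0][0]) + 2
                raise ValueError(f"{path}: negative distance at line {line}")
            out[str(pair_id)] = FISHDataset(
                pair_id=str(pair_id), distances=grp["distance_um"].to_numpy()
            )
        else:
            grp = grp.sort_values("r_um")
            out[str(pair_id)] = FISHDataset(
                pair_id=str(pair_id),
                cdf_r=grp["r_um"].to_numpy(),
                cdf_values=grp["cdf"].to_numpy(),
            )
    return out


def write_fish(datasets: dict[str, FISHDataset], path) -> None:
    """Write per-pair raw distances in the ``pair_id, distance_um`` dialect."""
    rows = []
    for pair_id, ds in datasets.items():
        if not ds.has_raw_distances:
            raise ValueError(f"pair {pair_id}: only raw-distance datasets can be written")
        rows.append(pd.DataFrame({"pair_id": pair_id, "distance_um": ds.distances}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_hic_counts(path) -> pd.Series:
    """Read per-pair Hi-C contact counts; returns a Series indexed by pair_id."""
    df = _read_table(path)
    _require_columns(df, path, ("pair_id", "contact_count"))
    if df["contact_count"].isna().any() or (df["contact_count"] < 0).any():
        bad = df.index[df["contact_count"].isna() | (df["contact_count"] < 0)][0]
        raise ValueError(f"{path}: missing or negative count at line {int(bad) + 2}")
    return df.set_index(df["pair_id"].astype(str))["contact_count"].astype(float)


def read_bedpe(path, N: Optional[int] = None, bin_size: int = DEFAULT_BIN_SIZE):
    """Read loop anchors from BEDPE and map them to monomer indices.

    Coordinates are 0-based half-open; each anchor maps to monomer
    ``floor(start / bin_size)``.  All anchors must be on one chromosome
    (the simulated chain).
    """
    from .simulate import LoopSet

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >= 6 BEDPE fields")
            chrom1, start1, _, chrom2, start2, _ = parts[:6]
            if chrom1 != chrom2:
                raise ValueError(
                    f"{path}: line {lineno}: inter-chromosomal loop not supported"
                )
            try:
                p = int(start1) // bin_size
                q = int(start2) // bin_size
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            pairs.append((p, q))
    if not pairs:
        raise ValueError(f"{path}: empty BEDPE input")
    loops = LoopSet(pairs)
    if N is not None:
        loops.validate(N)
    return loops


def read_loop_indices(path):
    """Read a two-column (p, q) monomer-index CSV into a LoopSet."""
    from .simulate import LoopSet

    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need two index columns")
    return LoopSet(df.iloc[:, :2].astype(int).itertuples(index=False, name=None))


def write_results(obj: dict, path) -> None:
    """Serialize a result record (with numpy scalars/arrays) as JSON."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def save_trajectory(traj, path) -> None:
    """Store trajectory snapshots plus run metadata in an .npz container."""
    from .simulate import Trajectory

    assert isinstance(traj, Trajectory)
    sys_ = traj.system
    np.savez_compressed(
        path,
        positions=traj.positions,
        dt=traj.dt,
        save_every=traj.save_every,
        seed=traj.seed,
        N=sys_.N,
        a=sys_.a,
        kappa=sys_.kappa,
        omega=sys_.omega,
        xi=sys_.xi,
        kT=sys_.kT,
        mass=sys_.mass,
        rest_length_mode=sys_.rest_length_mode,
        loops=np.array(sys_.loops.anchors, dtype=int).reshape(-1, 2),
    )


def load_trajectory(path):
    from .simulate import GRMCSystem, LoopSet, Trajectory

    with np.load(path, allow_pickle=False) as z:
        system = GRMCSystem(
            N=int(z["N"]),
            a=float(z["a"]),
            kappa=float(z["kappa"]),
            omega=float(z["omega"]),
            xi=float(z["xi"]),
            kT=float(z["kT"]),
            mass=float(z["mass"]),
            rest_length_mode=str(z["rest_length_mode"]),
            loops=LoopSet(z["loops"]),
        )
        return Trajectory(
            positions=z["positions"],
            dt=float(z["dt"]),
            save_every=int(z["save_every"]),
            seed=int(z["seed"]),
            system=system,
        )


def pipeline_reconcile(
    fish_table: dict[str, FISHDataset],
    hic_table: Union[pd.Series, dict],
    config: RunConfig,
) -> dict:
    """Fit FISH curves pair by pair and compare predicted vs Hi-C contact frequencies.

    Pairs present in only one of the two tables are reported and skipped.
    Returns a serializable report: per-pair fit parameters and diagnostics,
    relative contact frequencies from model and from Hi-C counts, and their
    Pearson correlation.
    """
    if isinstance(hic_table, dict):
        hic_table = pd.Series(hic_table, dtype=float)
    common = [p for p in fish_table if p in hic_table.index]
    skipped = sorted((set(fish_table) | set(map(str, hic_table.index))) - set(common))
    if len(common) < 2:
        raise ValueError(
            f"need at least two pairs present in both tables, got {len(common)}"
        )
    for pair in skipped:
        logger.warning("pair %s present in only one table; skipped", pair)

    per_pair = {}
    probs = []
    counts = []
    for pair in common:
        fit = fit_mixture(
            fish_table[pair],
            family=config.family,
            g=config.g,
            delta=config.delta,
            seed=config.seed,
        )
        P = mixture_contact_prob(fit.model, config.r_c)
        probs.append(P)
        counts.append(float(hic_table[pair]))
        per_pair[pair] = {
            "eta": fit.model.eta,
            "R1": fit.model.R1,
            "R2": fit.model.R2,
            "ks": fit.ks,
            "objective": fit.objective,
            "converged": fit.converged,
            "degenerate": fit.degenerate,
            "predicted_contact_prob": P,
            "hic_count": float(hic_table[pair]),
        }
        logger.info(
            "pair %s: eta=%.3f R1=%.3f R2=%.3f KS=%.4f P=%.3g",
            pair, fit.model.eta, fit.model.R1, fit.model.R2, fit.ks, P,
        )

    pred_rel = relative_contact_frequencies(probs)
    hic_rel = relative_contact_frequencies(counts)
    pearson = compare_to_hic(probs, counts)
    for pair, pr, hr in zip(common, pred_rel, hic_rel):
        per_pair[pair]["predicted_relative"] = float(pr)
        per_pair[pair]["hic_relative"] = float(hr)
    return {
        "config": config.provenance(),
        "pairs": per_pair,
        "skipped_pairs": skipped,
        "pearson_relative_frequency": pearson,
    }
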