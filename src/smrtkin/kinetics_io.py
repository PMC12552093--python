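"""Reading/writing kinetics tables and genomes, signal normalization and
subread averaging.

The kinetics TSV dialect is one record per (contig, position, strand):

    #contig  pos0  strand  ipd_mean  pw_mean  n_subreads

positions are 0-based, strands are '+'/'-', kinetic values are non-negative
reals.  In file-ingestion mode the ``*_mean`` columns are taken as already
subread-averaged.

Raw IPD/PW are normalized before any downstream modeling.  The default is
mean scaling (divide by the group mean), which keeps values positive so the
baseline-referenced ratio feature stays well defined; z-scoring is available
as an option.  The grouping scope is either per read (when per-read grouping
is available) or global over a whole track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

KINETICS_COLUMNS = ["contig", "pos0", "strand", "ipd_mean", "pw_mean", "n_subreads"]

__all__ = [
    "KineticTrack",
    "NormalizationSpec",
    "KINETICS_COLUMNS",
    "read_kinetics",
    "write_kinetics",
    "read_genome",
    "write_genome",
    "normalize_signals",
    "normalize_table",
    "average_subreads",
]


class KineticTrack(NamedTuple):
    """One per-site kinetic record (normalized or raw, context-dependent)."""

    contig: str
    pos: int
    strand: str
    ipd: float
    pw: float
    n_subreads: int


@dataclass(frozen=True)
class NormalizationSpec:
    """How raw kinetic signals are brought onto a common scale.

    method: 'mean_scale' divides by the group mean (values stay positive);
            'zscore' centers and scales by the group standard deviation.
    scope:  'per_read' or 'global' — the grouping over which statistics are
            computed ('global' treats the whole track as one group).
    epsilon guards divisions for degenerate groups.
    """

    method: str = "mean_scale"
    scope: str = "global"
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.method not in ("mean_scale", "zscore"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.scope not in ("per_read", "global"):
            raise ValueError(f"unknown normalization scope {self.scope!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def read_kinetics(path: str | Path) -> pd.DataFrame:
    """Read a kinetics TSV, validating records against the track invariants.

    Raises ValueError with a line number for malformed rows, negative kinetic
    values, bad strands, and duplicated (contig, pos0, strand) keys.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    expected = "#" + "\t".join(KINETICS_COLUMNS)
    if header.rstrip("\n") != expected:
        raise ValueError(f"{path}: header {header!r} does not match dialect {expected!r}")
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=1, names=KINETICS_COLUMNS,
                     dtype={"contig": str, "strand": str})
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.strand not in ("+", "-"):
            raise ValueError(f"{path}:{i}: invalid strand {row.strand!r}")
        if not np.isfinite(row.ipd_mean) or not np.isfinite(row.pw_mean):
            raise ValueError(f"{path}:{i}: non-finite kinetic value")
        if row.ipd_mean < 0 or row.pw_mean < 0:
            raise ValueError(f"{path}:{i}: negative kinetic value")
        if row.n_subreads < 1:
            raise ValueError(f"{path}:{i}: n_subreads must be >= 1")
    dup = df.duplicated(subset=["contig", "pos0", "strand"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValueError(
            f"{path}: duplicate record for ({first.contig}, {first.pos0}, {first.strand})")
    df["pos0"] = df["pos0"].astype(np.int64)
    df["n_subreads"] = df["n_subreads"].astype(np.int64)
    return df


def write_kinetics(df: pd.DataFrame, path: str | Path) -> None:
    """Write a kinetics table in the TSV dialect (6-decimal floats)."""
    missing = [c for c in KINETICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"kinetics table missing columns: {missing}")
    out = df[KINETICS_COLUMNS]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(KINETICS_COLUMNS) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6f")


def read_genome(path: str | Path) -> dict[str, str]:
    """FASTA -> {contig: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(contigs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def normalize_signals(values: Sequence[float] | np.ndarray,
                      groups: Sequence | np.ndarray | None,
                      spec: NormalizationSpec) -> np.ndarray:
    """Normalize values within groups (one statistic per group).

    ``groups=None`` treats all values as one group.  mean_scale divides by the
    group mean (epsilon-guarded); zscore maps a constant group to all zeros.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalize an empty value array")
    if groups is None:
        groups = np.zeros(len(values), dtype=np.int64)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    for g in pd.unique(groups):
        m = groups == g
        x = values[m]
        if spec.method == "mean_scale":
            mean = x.mean()
            out[m] = x / (mean if abs(mean) > spec.epsilon else spec.epsilon)
        else:
            sd = x.std()
            out[m] = (x - x.mean()) / (sd + spec.epsilon)
    return out


def normalize_table(df: pd.DataFrame, spec: NormalizationSpec) -> pd.DataFrame:
    """Normalize ipd_mean / pw_mean of a kinetics table.

    Global scope groups by contig (each contig's track is one group, the
    tabular analog of normalizing across all bases of the same read set).
    """
    out = df.copy()
    groups = df["contig"].to_numpy() if spec.scope == "global" else df["contig"].to_numpy()
    for col in ("ipd_mean", "pw_mean"):
        out[col] = normalize_signals(df[col].to_numpy(), groups, spec)
    return out


def average_subreads(subread_values: Iterable[np.ndarray | Sequence[float]],
                     min_coverage: int = 3) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average per-site subread measurements.

    Returns (means, counts, passes_min_coverage).  Empty sites are excluded
    with a log entry; the returned arrays cover the remaining sites in order.
    """
    means, counts = [], []
    n_empty = 0
    for vals in subread_values:
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            n_empty += 1
            continue
        means.append(arr.mean())
        counts.append(arr.size)
    if n_empty:
        logger.info("average_subreads: excluded %d empty sites", n_empty)
    means_a = np.array(means)
    counts_a = np.array(counts, dtype=np.int64)
    return means_a, counts_a, counts_a >= min_coverage
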