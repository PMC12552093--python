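"""Seeded simulator of genomes, motif-placed methylation truth and SMRT-like
polymerase kinetics (IPD / PW) with a known sequence-context ground truth.

The simulator is the test bed for the whole pipeline: it produces a random
genome, places methylated sites at occurrences of an IUPAC motif, and emits
per-site subread-averaged kinetic signals whose noiseless values come from a
known function of the local k-mer context.  A whole-genome-amplification (WGA)
mode — ``methyl_fraction=0`` — yields methylation-free data for training the
baseline kinetic regressor.

Ground-truth kinetic function
-----------------------------
The noiseless kinetic value of a base is a log-linear function of its k-mer
context: a per-position base effect, an adjacent-dinucleotide interaction
effect, and a small k-mer-specific residual, all drawn once from a seeded
normal distribution on the log scale (total log-sd ~0.35, median 1.0).  This
gives the regression stage learnable but non-trivial structure, mirroring the
strong dependence of real polymerase kinetics on nearby sequence.

Methylation perturbs the kinetics multiplicatively at configured offsets from
the modified base, on the modified strand only — prokaryotic methylation is
frequently strand-asymmetric and the simulator preserves that.  Two presets
bracket the biological regimes: a weak, 5mC-like shift and a strong,
6mA/4mC-like shift.

Subread observations are the noiseless value times lognormal noise
``exp(eps)``, ``eps ~ N(0, sigma)``, with a shifted-Poisson number of subreads
per site (minimum 1).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import kinetics_io

__all__ = [
    "SimConfig",
    "GroundTruthKinetics",
    "MethylationTruth",
    "SimulatedKinetics",
    "IUPAC",
    "WEAK_5MC_PRESET",
    "STRONG_6MA_PRESET",
    "generate_genome",
    "simulate_kinetics",
    "write_fixture",
    "simulate_dataset",
]

# IUPAC nucleotide codes -> the set of concrete bases each matches
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# Multiplicative kinetic shifts at offsets (in the strand's 5'->3' sense)
# relative to the modified base.  Weak ~ 5mC; strong ~ 6mA/4mC.
WEAK_5MC_PRESET: dict[str, dict[int, float]] = {
    "ipd": {0: 1.15, 1: 1.07},
    "pw": {0: 1.08},
}
STRONG_6MA_PRESET: dict[str, dict[int, float]] = {
    "ipd": {0: 2.5, 1: 1.5},
    "pw": {0: 1.4},
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Configuration of one simulated dataset.

    ``ipd_shift`` / ``pw_shift`` map relative offsets (0 = the modified base,
    positive = downstream in the strand's reading direction) to multiplicative
    kinetic effects applied to methylated sites.
    """

    genome_length: int = 20_000
    gc_content: float = 0.5
    motif: str = "CCWGG"
    mod_offset: int = 1
    methyl_fraction: float = 1.0
    context_k: int = 7
    ipd_shift: Mapping[int, float] = field(default_factory=lambda: dict(WEAK_5MC_PRESET["ipd"]))
    pw_shift: Mapping[int, float] = field(default_factory=lambda: dict(WEAK_5MC_PRESET["pw"]))
    subread_noise_sigma: float = 0.2
    coverage_mean: float = 10.0
    seed: int = 0
    # Seed of the ground-truth kinetic function (the "polymerase chemistry").
    # Defaults to `seed`; native and WGA datasets of the same experiment must
    # share it, since amplification changes methylation, not the polymerase.
    chemistry_seed: int | None = None
    contig: str = "sim_contig"

    def __post_init__(self) -> None:
        if not self.motif or any(b not in IUPAC for b in self.motif):
            raise ValueError(f"motif {self.motif!r} contains non-IUPAC characters")
        if not (0 <= self.mod_offset < len(self.motif)):
            raise ValueError("mod_offset must index a base within the motif")
        if self.context_k < 3 or self.context_k % 2 == 0:
            raise ValueError("context_k must be odd and >= 3")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if not (0.0 <= self.methyl_fraction <= 1.0):
            raise ValueError("methyl_fraction must lie in [0, 1]")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must lie in [0, 1]")
        if self.subread_noise_sigma < 0:
            raise ValueError("subread_noise_sigma must be >= 0")
        if self.genome_length < len(self.motif):
            raise ValueError("genome shorter than motif")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ipd_shift"] = {int(k): float(v) for k, v in self.ipd_shift.items()}
        d["pw_shift"] = {int(k): float(v) for k, v in self.pw_shift.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for key in ("ipd_shift", "pw_shift"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent RNG stream derived from the config seed."""
        key = zlib.crc32(stream.encode()) % (2 ** 31)
        return np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(key,)))


@dataclass(frozen=True)
class MethylSite:
    contig: str
    pos: int          # 0-based genomic coordinate of the modified base
    strand: str       # '+' or '-'
    mod_type: str


@dataclass
class MethylationTruth:
    sites: list[MethylSite]

    def __len__(self) -> int:
        return len(self.sites)

    def site_keys(self) -> set[tuple[str, int, str]]:
        return {(s.contig, s.pos, s.strand) for s in self.sites}


_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


class GroundTruthKinetics:
    """The known noiseless kinetic function: k-mer context -> (IPD, PW).

    log value = sum_i beta[i, base_i] + sum_i pair[i, base_i, base_{i+1}] + rho * residual(kmer)

    Position and dinucleotide effects are seeded draws; the residual is a
    deterministic per-k-mer hash-seeded normal so the same k-mer always maps to
    the same value without materializing all 4^k entries.
    """

    # log-sd budget: position ~0.25, pairs ~0.20, residual 0.08 -> total ~0.34
    POS_SD = 0.25
    PAIR_SD = 0.20
    RESID_SD = 0.08

    def __init__(self, context_k: int, seed: int):
        if context_k < 3 or context_k % 2 == 0:
            raise ValueError("context_k must be odd and >= 3")
        self.context_k = context_k
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(101,)))
        k = context_k
        # independent effect tables for the two kinetic channels
        self._pos = rng.normal(0.0, self.POS_SD / np.sqrt(k), size=(2, k, 4))
        self._pair = rng.normal(0.0, self.PAIR_SD / np.sqrt(k - 1), size=(2, k - 1, 4, 4))
        self._resid_seed = int(rng.integers(0, 2 ** 31))

    @classmethod
    def from_config(cls, cfg: SimConfig) -> "GroundTruthKinetics":
        chem = cfg.seed if cfg.chemistry_seed is None else cfg.chemistry_seed
        return cls(cfg.context_k, chem)

    def _residual(self, codes: np.ndarray) -> np.ndarray:
        """Deterministic per-k-mer standard-normal residual (n,) for code rows."""
        k = self.context_k
        idx = np.zeros(len(codes), dtype=np.int64)
        for i in range(k):
            idx = idx * 4 + codes[:, i]
        # hash each k-mer index with the table seed into a uniform, then probit
        x = (idx * 2654435761 + self._resid_seed) % (2 ** 31)
        u = (x.astype(np.float64) + 0.5) / (2 ** 31)
        from scipy.special import ndtri
        return ndtri(u)

    def values_for_codes(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """codes: (n, k) int array of base indices -> (ipd, pw) arrays (n,)."""
        k = self.context_k
        if codes.ndim != 2 or codes.shape[1] != k:
            raise ValueError(f"expected (n, {k}) code array")
        n = len(codes)
        resid = self._residual(codes)
        out = []
        for ch in range(2):
            logv = np.zeros(n)
            for i in range(k):
                logv += self._pos[ch, i, codes[:, i]]
            for i in range(k - 1):
                logv += self._pair[ch, i, codes[:, i], codes[:, i + 1]]
            logv += self.RESID_SD * resid * (1.0 if ch == 0 else -1.0)
            out.append(np.exp(logv))
        return out[0], out[1]

    def lookup(self, kmer: str) -> tuple[float, float]:
        """(mean IPD, mean PW) for one k-mer context."""
        if len(kmer) != self.context_k:
            raise ValueError("k-mer length mismatch")
        codes = np.array([[_BASE_INDEX[b] for b in kmer]])
        ipd, pw = self.values_for_codes(codes)
        return float(ipd[0]), float(pw[0])


def find_motif_sites(seq: str, motif: str, mod_offset: int, contig: str = "sim_contig",
                     mod_type: str = "mod") -> list[MethylSite]:
    """All occurrences of an IUPAC motif on both strands; returns the genomic
    position of the modified base per occurrence.

    Minus-strand occurrences are matches of the reverse-complemented motif on
    the given sequence; the modified base then sits at
    ``match_start + len(motif) - 1 - mod_offset``.
    """
    sites: list[MethylSite] = []
    m = len(motif)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    for strand, pat in (("+", motif), ("-", reverse_complement(motif))):
        mask = np.ones(len(seq) - m + 1, dtype=bool) if len(seq) >= m else np.zeros(0, dtype=bool)
        for j, code in enumerate(pat):
            allowed = np.frombuffer("".join(sorted(IUPAC[code])).encode(), dtype="S1")
            mask &= np.isin(arr[j:j + len(mask)], allowed)
        starts = np.nonzero(mask)[0]
        offset = mod_offset if strand == "+" else m - 1 - mod_offset
        for s in starts:
            sites.append(MethylSite(contig, int(s) + offset, strand, mod_type))
    sites.sort(key=lambda s: (s.pos, s.strand))
    return sites


def generate_genome(cfg: SimConfig) -> tuple[str, MethylationTruth]:
    """Random genome of the requested length/GC plus seeded methylation truth.

    A seeded subset of ``round(methyl_fraction * n_sites)`` motif occurrences
    (both strands) is marked methylated.  ``methyl_fraction=0`` is WGA mode.
    """
    rng = cfg.rng("genome")
    p = np.array([(1 - cfg.gc_content) / 2, cfg.gc_content / 2,
                  cfg.gc_content / 2, (1 - cfg.gc_content) / 2])
    seq = "".join(rng.choice(_BASES, size=cfg.genome_length, p=p))
    all_sites = find_motif_sites(seq, cfg.motif, cfg.mod_offset, cfg.contig)
    if not all_sites:
        warnings.warn(f"motif {cfg.motif} not found in simulated genome; empty truth")
        return seq, MethylationTruth([])
    n_mod = int(round(cfg.methyl_fraction * len(all_sites)))
    pick = cfg.rng("truth").choice(len(all_sites), size=n_mod, replace=False)
    chosen = [all_sites[i] for i in sorted(pick)]
    return seq, MethylationTruth(chosen)


@dataclass
class SimulatedKinetics:
    """Per-position kinetics for both strands of one contig.

    Arrays are genome-length; ``valid`` is False within ``context_k // 2`` of
    the contig ends, where the k-mer context is undefined.  ``ipd``/``pw``
    hold subread-averaged observed values; ``*_noiseless`` the ground truth
    including any methylation shift.
    """

    contig: str
    ipd: dict[str, np.ndarray]
    pw: dict[str, np.ndarray]
    n_subreads: dict[str, np.ndarray]
    ipd_noiseless: dict[str, np.ndarray]
    pw_noiseless: dict[str, np.ndarray]
    valid: np.ndarray

    def to_table(self):
        """Long-format kinetics table (one row per valid position and strand)."""
        import pandas as pd
        rows = []
        for strand in "+-":
            idx = np.nonzero(self.valid)[0]
            rows.append(pd.DataFrame({
                "contig": self.contig,
                "pos0": idx,
                "strand": strand,
                "ipd_mean": self.ipd[strand][idx],
                "pw_mean": self.pw[strand][idx],
                "n_subreads": self.n_subreads[strand][idx],
            }))
        return pd.concat(rows, ignore_index=True)


def _context_codes(seq: str, strand: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Valid positions and their (n, k) context codes on one strand.

    The minus-strand context of genomic position p is the reverse complement
    of the plus-strand window centered on p.
    """
    L = len(seq)
    flank = k // 2
    codes1 = np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int64, count=L)
    pos = np.arange(flank, L - flank)
    windows = np.stack([codes1[pos + d] for d in range(-flank, flank + 1)], axis=1)
    if strand == "-":
        windows = 3 - windows[:, ::-1]
    return pos, windows


def _shift_vector(L: int, truth: MethylationTruth, strand: str,
                  shift: Mapping[int, float]) -> np.ndarray:
    """Multiplicative shift per genomic position for one strand's kinetics."""
    out = np.ones(L)
    for site in truth.sites:
        if site.strand != strand:
            continue
        for off, mult in shift.items():
            p = site.pos + off if strand == "+" else site.pos - off
            if 0 <= p < L:
                out[p] *= mult
    return out


def simulate_kinetics(seq: str, truth: MethylationTruth, cfg: SimConfig,
                      ground_truth: GroundTruthKinetics | None = None) -> SimulatedKinetics:
    """Subread-averaged IPD/PW per position and strand, plus noiseless means.

    Observed subread value = noiseless * exp(eps), eps ~ N(0, sigma); subread
    count ~ 1 + Poisson(coverage_mean - 1).  With ``subread_noise_sigma=0``
    and coverage 1 the emitted value equals the noiseless mean exactly.
    """
    gt = ground_truth or GroundTruthKinetics.from_config(cfg)
    if gt.context_k != cfg.context_k:
        raise ValueError("ground-truth context width disagrees with config")
    L = len(seq)
    flank = cfg.context_k // 2
    valid = np.zeros(L, dtype=bool)
    valid[flank:L - flank] = True
    rng = cfg.rng("kinetics")
    ipd: dict[str, np.ndarray] = {}
    pw: dict[str, np.ndarray] = {}
    nsub: dict[str, np.ndarray] = {}
    ipd_nl: dict[str, np.ndarray] = {}
    pw_nl: dict[str, np.ndarray] = {}
    for strand in "+-":
        pos, codes = _context_codes(seq, strand, cfg.context_k)
        base_ipd, base_pw = gt.values_for_codes(codes)
        si = _shift_vector(L, truth, strand, cfg.ipd_shift)[pos]
        sp = _shift_vector(L, truth, strand, cfg.pw_shift)[pos]
        nl_i = base_ipd * si
        nl_p = base_pw * sp
        if cfg.coverage_mean == 1:
            counts = np.ones(len(pos), dtype=np.int64)
        else:
            counts = 1 + rng.poisson(cfg.coverage_mean - 1.0, size=len(pos))
        obs_i = np.empty(len(pos))
        obs_p = np.empty(len(pos))
        if cfg.subread_noise_sigma == 0:
            obs_i, obs_p = nl_i.copy(), nl_p.copy()
        else:
            total = int(counts.sum())
            eps_i = rng.normal(0.0, cfg.subread_noise_sigma, size=total)
            eps_p = rng.normal(0.0, cfg.subread_noise_sigma, size=total)
            bounds = np.concatenate([[0], np.cumsum(counts)])
            mult_i = np.exp(eps_i)
            mult_p = np.exp(eps_p)
            sums_i = np.add.reduceat(mult_i, bounds[:-1])
            sums_p = np.add.reduceat(mult_p, bounds[:-1])
            obs_i = nl_i * sums_i / counts
            obs_p = nl_p * sums_p / counts
        full = lambda vals: np.concatenate([np.full(flank, np.nan), vals, np.full(flank, np.nan)])
        ipd[strand] = full(obs_i)
        pw[strand] = full(obs_p)
        ipd_nl[strand] = full(nl_i)
        pw_nl[strand] = full(nl_p)
        c = np.zeros(L, dtype=np.int64)
        c[pos] = counts
        nsub[strand] = c
    return SimulatedKinetics(cfg.contig, ipd, pw, nsub, ipd_nl, pw_nl, valid)


def simulate_dataset(cfg: SimConfig) -> tuple[str, MethylationTruth, SimulatedKinetics]:
    """Convenience: genome + truth + kinetics in one seeded call."""
    seq, truth = generate_genome(cfg)
    kin = simulate_kinetics(seq, truth, cfg)
    return seq, truth, kin


def write_fixture(outdir: str | Path, seq: str, truth: MethylationTruth,
                  kin: SimulatedKinetics, cfg: SimConfig) -> dict[str, Path]:
    """Write genome FASTA, kinetics TSV, truth BED6 and the config YAML.

    BED intervals are 0-based half-open of width 1 around the modified base.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "kinetics": outdir / "kinetics.tsv",
        "bed": outdir / "truth.bed",
        "config": outdir / "sim_config.yaml",
    }
    kinetics_io.write_genome({cfg.contig: seq}, paths["fasta"])
    kinetics_io.write_kinetics(kin.to_table(), paths["kinetics"])
    with open(paths["bed"], "w") as fh:
        for s in truth.sites:
            fh.write(f"{s.contig}\t{s.pos}\t{s.pos + 1}\t{s.mod_type}\t0\t{s.strand}\n")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return paths


def read_truth_bed(path: str | Path) -> MethylationTruth:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            contig, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            if int(end) - int(start) != 1:
                raise ValueError(f"truth BED interval wider than 1 base: {line!r}")
            sites.append(MethylSite(contig, int(start), strand, name))
    return MethylationTruth(sites)
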