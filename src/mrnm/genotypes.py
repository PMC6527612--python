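"""Genotype simulation, genomic relationship matrices, and PLINK/GCTA file IO.

The genomic relationship matrix (GRM) ``A`` is the standard GREML-family
relatedness estimate

    A = W W' / m,   W[i, j] = (x[i, j] - 2 p_j) / sqrt(2 p_j (1 - p_j)),

where ``x`` are allele counts in {0, 1, 2}, ``p_j`` is the sample allele
frequency of SNP j and ``m`` the number of SNPs retained after MAF filtering.
Allele frequencies used for standardisation are always estimated from the
analysed sample.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("mrnm")

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "simulate_genotypes",
    "compute_grm",
    "prune_related",
    "read_plink",
    "write_plink",
    "read_grm_bin",
    "write_grm_bin",
    "read_grm_text",
    "write_grm_text",
]


@dataclass
class GenotypeMatrix:
    """Allele-count matrix (n individuals x m SNPs, entries in {0, 1, 2})."""

    counts: np.ndarray
    ids: list[str]
    snp_ids: list[str]
    freqs: np.ndarray  # per-SNP frequency of the counted allele

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.freqs = np.asarray(self.freqs, dtype=float)
        n, m = self.counts.shape
        if n < 2 or m < 1:
            raise ValueError(f"need n >= 2 individuals and m >= 1 SNPs, got {n}x{m}")
        if not np.isin(self.counts, (0, 1, 2)).all():
            raise ValueError("genotype counts must be in {0, 1, 2}")
        if len(self.ids) != n or len(self.snp_ids) != m or len(self.freqs) != m:
            raise ValueError("id/frequency lengths inconsistent with count matrix")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    def sample_freqs(self) -> np.ndarray:
        """Allele frequencies estimated from the sample (mean count / 2)."""
        return self.counts.mean(axis=0) / 2.0


@dataclass
class GRM:
    """Symmetric n x n genomic relationship matrix with individual ids."""

    values: np.ndarray
    ids: list[str]
    n_snps: int
    _eig: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.ids) != n:
            raise ValueError("id count must match GRM dimension")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition (w, U), cached; negative eigenvalues clipped at 0."""
        if self._eig is None:
            w, U = np.linalg.eigh(self.values)
            self._eig = (np.clip(w, 0.0, None), U)
        return self._eig

    def sqrt(self) -> np.ndarray:
        """A^(1/2) via eigendecomposition, for drawing correlated effects."""
        w, U = self.eig()
        return U * np.sqrt(w)

    def submatrix(self, keep: list[str]) -> "GRM":
        idx = [self.ids.index(i) for i in keep]
        return GRM(self.values[np.ix_(idx, idx)], list(keep), self.n_snps)


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Simulate unlinked SNP genotypes in Hardy-Weinberg proportions.

    Each SNP j gets a frequency p_j drawn uniformly from ``maf_range``, and each
    individual's count is the sum of two independent Bernoulli(p_j) allele
    draws.  No linkage disequilibrium is simulated.
    """
    lo, hi = maf_range
    if n < 2 or m < 1:
        raise ValueError(f"need n >= 2 and m >= 1, got n={n}, m={m}")
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=m)
    counts = (
        (rng.random((n, m)) < freqs).astype(np.int8)
        + (rng.random((n, m)) < freqs).astype(np.int8)
    )
    ids = [f"id{i + 1}" for i in range(n)]
    snp_ids = [f"snp{j + 1}" for j in range(m)]
    return GenotypeMatrix(counts, ids, snp_ids, freqs)


def compute_grm(G: GenotypeMatrix, maf_min: float = 0.0) -> GRM:
    """Compute A = W W' / m' from sample-standardised genotypes.

    SNPs with sample MAF below ``maf_min`` are dropped; monomorphic SNPs are
    always dropped (with a warning) to avoid division by zero.
    """
    p = G.sample_freqs()
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= max(maf_min, 0.0)
    mono = (maf == 0.0) & keep
    if mono.any():
        logger.warning("dropping %d monomorphic SNPs from GRM", int(mono.sum()))
        keep &= ~mono
    m_kept = int(keep.sum())
    if m_kept == 0:
        raise ValueError("no SNPs remain after MAF filtering")
    pk = p[keep]
    W = (G.counts[:, keep] - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
    A = (W @ W.T) / m_kept
    A = (A + A.T) / 2.0
    return GRM(A, list(G.ids), m_kept)


def prune_related(
    A: GRM, threshold: float = 0.05, seed: int | np.random.Generator = 0
) -> list[str]:
    """Greedily drop one random member of each pair with relatedness > threshold.

    Returns the retained ids (GRM order).  The signed GRM entry is compared
    against the threshold, and the removed member of each offending pair is
    chosen at random, so repeated runs with different seeds can retain
    different (equally valid) subsets.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rng = np.random.default_rng(seed)
    vals = A.values
    active = np.ones(A.n, dtype=bool)
    off = vals - np.diag(np.diag(vals))
    while True:
        sub = np.where(active)[0]
        block = off[np.ix_(sub, sub)]
        ii, jj = np.nonzero(np.triu(block, 1) > threshold)
        if len(ii) == 0:
            break
        k = rng.integers(len(ii))
        pair = (sub[ii[k]], sub[jj[k]])
        active[pair[rng.integers(2)]] = False
    return [A.ids[i] for i in np.where(active)[0]]


# ---------------------------------------------------------------------------
# PLINK binary genotypes (.bed/.bim/.fam, SNP-major)
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit codes, SNP-major: 0b00 hom A1 (count 2), 0b10 het (1), 0b11 hom A2 (0),
# 0b01 missing.
_CODE_TO_COUNT = np.array([2, -1, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write genotypes as a PLINK binary trio (SNP-major .bed, .bim, .fam)."""
    prefix = Path(prefix)
    n, m = G.n, G.m
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid in G.ids:
            fh.write(f"{iid} {iid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, sid in enumerate(G.snp_ids):
            fh.write(f"1 {sid} 0 {j + 1} A B\n")
    codes = np.empty((m, n), dtype=np.uint8)
    cnt = G.counts.T
    for count, code in _COUNT_TO_CODE.items():
        codes[cnt == count] = code
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    packed[:, :n] = codes
    packed = packed.reshape(m, n_bytes, 4)
    out = (
        packed[:, :, 0]
        | (packed[:, :, 1] << 2)
        | (packed[:, :, 2] << 4)
        | (packed[:, :, 3] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.astype(np.uint8).tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK binary trio (SNP-major .bed dialect only)."""
    prefix = Path(prefix)
    ids = []
    with open(prefix.with_suffix(".fam")) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                ids.append(parts[1])
    snp_ids = []
    with open(prefix.with_suffix(".bim")) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                snp_ids.append(parts[1])
    n, m = len(ids), len(snp_ids)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK binary file")
    n_bytes = (n + 3) // 4
    body = raw[3 : 3 + m * n_bytes].reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    counts = _CODE_TO_COUNT[codes[:, :n]].T
    if (counts < 0).any():
        raise ValueError("missing genotypes are not supported")
    freqs = counts.mean(axis=0) / 2.0
    return GenotypeMatrix(counts, ids, snp_ids, freqs)


# ---------------------------------------------------------------------------
# GCTA GRM dialects
# ---------------------------------------------------------------------------


def write_grm_bin(A: GRM, prefix: str | Path) -> None:
    """Write GCTA binary GRM (.grm.bin/.grm.N.bin float32, .grm.id)."""
    prefix = Path(prefix)
    n = A.n
    tri = A.values[np.tril_indices(n)]
    tri.astype("<f4").tofile(f"{prefix}.grm.bin")
    np.full(tri.shape, A.n_snps, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in A.ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm_bin(prefix: str | Path) -> GRM:
    prefix = Path(prefix)
    ids = []
    with open(f"{prefix}.grm.id") as fh:
        for line in fh:
            parts = line.split()
            if parts:
                ids.append(parts[1])
    n = len(ids)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4").astype(float)
    if tri.size != n * (n + 1) // 2:
        raise ValueError("GRM binary size inconsistent with id file")
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    vals = np.zeros((n, n))
    vals[np.tril_indices(n)] = tri
    vals = vals + np.tril(vals, -1).T
    return GRM(vals, ids, int(round(float(counts[0]))) if counts.size else 0)


def write_grm_text(A: GRM, path: str | Path) -> None:
    """Plain-text lower triangle: columns i, j (1-based), n_snps, value."""
    with open(path, "w") as fh:
        for i in range(A.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{A.n_snps}\t{A.values[i, j]:.10g}\n")


def read_grm_text(path: str | Path, ids: list[str] | None = None) -> GRM:
    rows = np.loadtxt(path, ndmin=2)
    n = int(rows[:, 0].max())
    vals = np.zeros((n, n))
    for i, j, _, v in rows:
        vals[int(i) - 1, int(j) - 1] = v
        vals[int(j) - 1, int(i) - 1] = v
    n_snps = int(rows[0, 2])
    if ids is None:
        ids = [f"id{i + 1}" for i in range(n)]
    return GRM(vals, ids, n_snps)
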