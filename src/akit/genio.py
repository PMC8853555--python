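"""Genotype I/O, site filtering, allele frequencies and jackknife blocks.

Genotypes are held as a :class:`GenotypeMatrix`: a samples x SNPs array of
diploid calls counting copies of ``allele1`` (0/1/2, ``MISSING`` = -1),
with SNP and sample metadata as pandas DataFrames.  Two on-disk dialects
are supported:

* EIGENSTRAT: ``.geno`` (one text line per SNP, one digit per sample,
  9 = missing), ``.snp`` (id, chromosome, genetic position in Morgans,
  physical position, allele1, allele2), ``.ind`` (id, sex, population).
* PLINK binary: ``.bed``/``.bim``/``.fam`` with the standard SNP-major
  two-bit encoding; the ``.bim`` genetic-distance column is read as
  centiMorgans and converted to Morgans.

Downstream statistics consume per-population allele counts
(:class:`FreqTable`) and a contiguous genomic :class:`BlockPartition`
used for the weighted block jackknife.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

SNP_COLUMNS = ["snp_id", "chromosome", "genetic_pos", "physical_pos", "allele1", "allele2"]
SAMPLE_COLUMNS = ["sample_id", "population"]

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GenotypeFormatError(ValueError):
    """Raised when component files are inconsistent or contain bad symbols."""


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls with SNP and sample metadata.

    calls[i, j] counts copies of allele1 of SNP j carried by sample i;
    -1 marks a missing call.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise GenotypeFormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeFormatError(f"invalid call {self.calls[i, j]} at sample {i}, SNP {j}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples.reset_index(drop=True),
            self.snps.iloc[index].reset_index(drop=True),
            self.calls[:, index],
        )


@dataclass
class FreqTable:
    """Per-population allele1 counts, totals and frequencies.

    ``freq`` is NaN where a population has no observed alleles at a SNP
    (total = 0); statistics treat such entries as undefined.
    """

    populations: list[str]
    snps: pd.DataFrame
    count1: np.ndarray  # populations x snps
    total: np.ndarray   # populations x snps; 2 x non-missing samples

    def __post_init__(self) -> None:
        self.count1 = np.asarray(self.count1, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.count1.shape != self.total.shape or self.count1.shape[0] != len(self.populations):
            raise ValueError("count1/total shape mismatch")
        if (self.count1 < 0).any() or (self.count1 > self.total).any():
            raise ValueError("count1 must satisfy 0 <= count1 <= total")

    @property
    def freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.count1 / np.maximum(self.total, 1), np.nan)

    @property
    def n_snps(self) -> int:
        return self.count1.shape[1]

    def index_of(self, pops: list[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.populations)}
        try:
            return np.array([lookup[p] for p in pops], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown population {exc.args[0]!r}; known: {self.populations}") from None


@dataclass
class BlockPartition:
    """Contiguous jackknife blocks of SNPs within chromosomes."""

    block_of: np.ndarray  # snp index -> block index
    block_span: float     # Morgans (or base pairs if the physical fallback fired)

    def __post_init__(self) -> None:
        self.block_of = np.asarray(self.block_of, dtype=np.int64)

    @property
    def n_blocks(self) -> int:
        return int(self.block_of.max()) + 1 if self.block_of.size else 0

    @property
    def block_sizes(self) -> np.ndarray:
        return np.bincount(self.block_of, minlength=self.n_blocks)


# ---------------------------------------------------------------------------
# readers / writers

def _p(prefix: Path, ext: str) -> Path:
    return prefix.parent / (prefix.name + ext)


def read_genotypes(prefix: str | Path, format: str = "eigenstrat") -> GenotypeMatrix:
    """Read a genotype dataset from ``prefix`` in the given dialect."""
    prefix = Path(prefix)
    if format == "eigenstrat":
        return _read_eigenstrat(prefix)
    if format == "plink":
        return _read_plink(prefix)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(G: GenotypeMatrix, prefix: str | Path, format: str = "eigenstrat") -> None:
    """Write ``G`` so that :func:`read_genotypes` round-trips it exactly."""
    if G.n_samples == 0 or G.n_snps == 0:
        raise ValueError("refusing to write a genotype matrix with no samples or no SNPs")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "eigenstrat":
        _write_eigenstrat(G, prefix)
    elif format == "plink":
        _write_plink(G, prefix)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_snp_table(path: Path) -> pd.DataFrame:
    snps = pd.read_csv(
        path, sep=r"\s+", header=None, names=SNP_COLUMNS,
        dtype={"snp_id": str, "chromosome": str, "allele1": str, "allele2": str},
    )
    snps["genetic_pos"] = snps["genetic_pos"].astype(float)
    snps["physical_pos"] = snps["physical_pos"].astype(np.int64)
    return snps


def _read_eigenstrat(prefix: Path) -> GenotypeMatrix:
    snps = _read_snp_table(_p(prefix, ".snp"))
    ind = pd.read_csv(_p(prefix, ".ind"), sep=r"\s+", header=None,
                      names=["sample_id", "sex", "population"], dtype=str)
    samples = ind[["sample_id", "population"]].copy()
    lines = _p(prefix, ".geno").read_text().split()
    if len(lines) != len(snps):
        raise GenotypeFormatError(
            f"{prefix}.geno has {len(lines)} SNP lines but {prefix}.snp has {len(snps)}")
    calls = np.empty((len(samples), len(snps)), dtype=np.int8)
    for j, line in enumerate(lines):
        if len(line) != len(samples):
            raise GenotypeFormatError(
                f"{prefix}.geno line {j + 1} has {len(line)} calls for {len(samples)} samples")
        row = np.frombuffer(line.encode("ascii"), dtype=np.uint8).astype(np.int16) - ord("0")
        bad = ~np.isin(row, (0, 1, 2, 9))
        if bad.any():
            raise GenotypeFormatError(
                f"{prefix}.geno: unknown genotype symbol {line[int(np.argmax(bad))]!r} "
                f"at SNP line {j + 1}, sample column {int(np.argmax(bad)) + 1}")
        calls[:, j] = np.where(row == 9, MISSING, row)
    return GenotypeMatrix(samples, snps, calls)


def _write_eigenstrat(G: GenotypeMatrix, prefix: Path) -> None:
    body = np.where(G.calls == MISSING, 9, G.calls).astype(np.uint8) + ord("0")
    with open(_p(prefix, ".geno"), "wb") as fh:
        for j in range(G.n_snps):
            fh.write(body[:, j].tobytes())
            fh.write(b"\n")
    G.snps.to_csv(_p(prefix, ".snp"), sep="\t", header=False, index=False,
                  columns=SNP_COLUMNS)
    ind = pd.DataFrame({"sample_id": G.samples["sample_id"], "sex": "U",
                        "population": G.samples["population"]})
    ind.to_csv(_p(prefix, ".ind"), sep="\t", header=False, index=False)


# PLINK two-bit codes (per pair of bits, little-endian within a byte):
# 00 = hom allele1 (call 2), 10 = het (1), 11 = hom allele2 (0), 01 = missing.
_PLINK_DECODE = np.full(4, MISSING, dtype=np.int8)
_PLINK_DECODE[0b00] = 2
_PLINK_DECODE[0b10] = 1
_PLINK_DECODE[0b11] = 0
_PLINK_ENCODE = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}


def _read_plink(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(_p(prefix, ".bim"), sep=r"\s+", header=None,
                      names=["chromosome", "snp_id", "genetic_pos", "physical_pos",
                             "allele1", "allele2"],
                      dtype={"chromosome": str, "snp_id": str, "allele1": str, "allele2": str})
    bim["genetic_pos"] = bim["genetic_pos"].astype(float) / 100.0  # cM -> Morgans
    bim["physical_pos"] = bim["physical_pos"].astype(np.int64)
    snps = bim[SNP_COLUMNS]
    fam = pd.read_csv(_p(prefix, ".fam"), sep=r"\s+", header=None,
                      names=["population", "sample_id", "pat", "mat", "sex", "pheno"], dtype=str)
    samples = fam[["sample_id", "population"]].copy()
    n, m = len(samples), len(snps)
    raw = np.fromfile(_p(prefix, ".bed"), dtype=np.uint8)
    if raw.size < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise GenotypeFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != 0x01:
        raise GenotypeFormatError(f"{prefix}.bed: only SNP-major layout is supported")
    bpr = (n + 3) // 4  # bytes per SNP row
    if raw.size - 3 != bpr * m:
        raise GenotypeFormatError(
            f"{prefix}.bed has {raw.size - 3} data bytes; expected {bpr * m} "
            f"for {n} samples x {m} SNPs")
    body = raw[3:].reshape(m, bpr)
    # unpack two-bit fields, sample-fastest
    shifts = np.arange(4, dtype=np.uint8) * 2
    two_bit = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    calls = _PLINK_DECODE[two_bit.reshape(m, bpr * 4)[:, :n]]
    return GenotypeMatrix(samples, snps, np.ascontiguousarray(calls.T))


def _write_plink(G: GenotypeMatrix, prefix: Path) -> None:
    bim = pd.DataFrame({
        "chromosome": G.snps["chromosome"],
        "snp_id": G.snps["snp_id"],
        "genetic_pos": G.snps["genetic_pos"] * 100.0,  # Morgans -> cM
        "physical_pos": G.snps["physical_pos"],
        "allele1": G.snps["allele1"],
        "allele2": G.snps["allele2"],
    })
    bim.to_csv(_p(prefix, ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({"fid": G.samples["population"], "sample_id": G.samples["sample_id"],
                        "pat": "0", "mat": "0", "sex": "0", "pheno": "-9"})
    fam.to_csv(_p(prefix, ".fam"), sep="\t", header=False, index=False)
    n, m = G.n_samples, G.n_snps
    bpr = (n + 3) // 4
    codes = np.empty((m, bpr * 4), dtype=np.uint8)
    codes[:] = 0
    enc = np.zeros(4, dtype=np.uint8)
    for call, code in _PLINK_ENCODE.items():
        enc[call % 4] = code  # MISSING=-1 -> index 3
    codes[:, :n] = enc[(G.calls.T % 4)]
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (codes.reshape(m, bpr, 4) << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(_p(prefix, ".bed"), "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# filtering / summaries

def filter_sites(G: GenotypeMatrix, max_missing: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs whose missing-call fraction is <= ``max_missing`` (inclusive)."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must lie in [0, 1]")
    miss_frac = (G.calls == MISSING).mean(axis=0)
    return G.take_snps(np.flatnonzero(miss_frac <= max_missing))


def ld_prune(G: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.5) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on squared genotype correlation.

    Within each window position, every pair of still-kept SNPs with
    pairwise-complete r^2 > ``r2_max`` loses its later-indexed member;
    the window then advances by ``step`` SNPs.  Deterministic for a fixed
    input order; SNPs must be sorted by chromosome then physical position.
    """
    if window < step:
        raise ValueError("window must be >= step")
    calls = G.calls.astype(float)
    calls[G.calls == MISSING] = np.nan
    keep = np.ones(G.n_snps, dtype=bool)
    chrom = G.snps["chromosome"].to_numpy()
    for lo_chrom in pd.unique(chrom):
        idx = np.flatnonzero(chrom == lo_chrom)
        start = 0
        while start < len(idx):
            win = idx[start:start + window]
            live = win[keep[win]]
            for a_pos in range(len(live)):
                a = live[a_pos]
                if not keep[a]:
                    continue
                for b in live[a_pos + 1:]:
                    if not keep[b]:
                        continue
                    if _r2(calls[:, a], calls[:, b]) > r2_max:
                        keep[b] = False
            if start + window >= len(idx):
                break
            start += step
    return G.take_snps(np.flatnonzero(keep))


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def pop_freqs(G: GenotypeMatrix, populations: list[str] | None = None) -> FreqTable:
    """Per-population allele1 counts and totals from non-missing calls."""
    if populations is None:
        populations = G.populations()
    known = set(G.samples["population"])
    unknown = [p for p in populations if p not in known]
    if unknown:
        raise KeyError(f"unknown population(s) {unknown}; known: {sorted(known)}")
    count1 = np.zeros((len(populations), G.n_snps), dtype=np.int64)
    total = np.zeros_like(count1)
    pop_col = G.samples["population"].to_numpy()
    for i, pop in enumerate(populations):
        sub = G.calls[pop_col == pop]
        obs = sub != MISSING
        count1[i] = np.where(obs, sub, 0).sum(axis=0)
        total[i] = 2 * obs.sum(axis=0)
    return FreqTable(list(populations), G.snps.reset_index(drop=True), count1, total)


def assign_blocks(snps: pd.DataFrame, block_span: float = 0.05) -> BlockPartition:
    """Partition SNPs into contiguous start-anchored genomic blocks.

    A block opens at its first SNP's genetic position and accepts SNPs
    within ``block_span`` Morgans of that anchor; blocks never cross a
    chromosome boundary.  If genetic positions are absent (all zero),
    falls back to 5 Mb physical spans and warns.
    """
    if block_span < 0:
        raise ValueError("block_span must be non-negative")
    pos = snps["genetic_pos"].to_numpy(dtype=float)
    if np.allclose(pos, 0.0) and len(pos) > 1:
        warnings.warn("no genetic positions; falling back to 5 Mb physical blocks")
        pos = snps["physical_pos"].to_numpy(dtype=float)
        block_span = 5e6
    chrom = snps["chromosome"].to_numpy()
    block_of = np.empty(len(snps), dtype=np.int64)
    block = -1
    anchor = None
    prev_chrom = None
    for j in range(len(snps)):
        if chrom[j] != prev_chrom or pos[j] - anchor > block_span:
            block += 1
            anchor = pos[j]
            prev_chrom = chrom[j]
        block_of[j] = block
    return BlockPartition(block_of, block_span)


# ---------------------------------------------------------------------------
# dataset merging

def merge_datasets(A: GenotypeMatrix, B: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two datasets on their shared SNP ids.

    Alleles are harmonized by allele-pair match, allowing an
    allele1/allele2 swap (B's calls are flipped 2 - g); SNPs whose allele
    pairs do not match either way, and strand-ambiguous A/T or C/G
    mismatches, are dropped.
    """
    a_idx = {s: j for j, s in enumerate(A.snps["snp_id"])}
    keep_a, keep_b, flip = [], [], []
    for j, row in enumerate(B.snps.itertuples(index=False)):
        i = a_idx.get(row.snp_id)
        if i is None:
            continue
        a1, a2 = A.snps["allele1"].iat[i], A.snps["allele2"].iat[i]
        if (row.allele1, row.allele2) == (a1, a2):
            fl = False
        elif (row.allele1, row.allele2) == (a2, a1):
            if _COMPLEMENT.get(a1) == a2:  # strand-ambiguous swap: unresolvable
                continue
            fl = True
        else:
            continue
        keep_a.append(i)
        keep_b.append(j)
        flip.append(fl)
    keep_a = np.array(keep_a, dtype=int)
    keep_b = np.array(keep_b, dtype=int)
    flip = np.array(flip, dtype=bool)
    calls_b = B.calls[:, keep_b].copy()
    if flip.any():
        flipped = calls_b[:, flip]
        calls_b[:, flip] = np.where(flipped == MISSING, MISSING, 2 - flipped)
    samples = pd.concat([A.samples, B.samples], ignore_index=True)
    calls = np.vstack([A.calls[:, keep_a], calls_b])
    return GenotypeMatrix(samples, A.snps.iloc[keep_a].reset_index(drop=True), calls)
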