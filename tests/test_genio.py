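import numpy as np
import pandas as pd
import pytest

from akit import genio
from akit.genio import MISSING

from conftest import make_snp_table, random_matrix


# ---------------------------------------------------------------------------
# readers / writers

def test_eigenstrat_digit_decode(tmp_path):
    """geno digits count copies of allele1; 9 decodes to missing."""
    (tmp_path / "x.geno").write_text("02\n19\n20\n")
    make_snp_table(3).to_csv(tmp_path / "x.snp", sep="\t", header=False, index=False)
    (tmp_path / "x.ind").write_text("i1 U P1\ni2 U P2\n")
    G = genio.read_genotypes(tmp_path / "x", "eigenstrat")
    assert G.calls.tolist() == [[0, 1, 2], [2, MISSING, 0]]
    assert list(G.samples["population"]) == ["P1", "P2"]


def test_plink_matches_eigenstrat_decode(tmp_path, tiny_matrix):
    """Hand-packed .bed bytes decode to the same calls as the geno digits."""
    # two-bit codes, sample-fastest within each SNP byte:
    # SNP0: s1=0 copies (11), s2=2 (00) -> 0b00000011; SNP1: s1=1 (10), s2=miss (01)
    # -> 0b00000110; SNP2: s1=2 (00), s2=0 (11) -> 0b00001100
    bed = bytes([0x6C, 0x1B, 0x01, 0b00000011, 0b00000110, 0b00001100])
    (tmp_path / "x.bed").write_bytes(bed)
    snps = tiny_matrix.snps
    bim = snps[["chromosome", "snp_id"]].copy()
    bim["cm"] = snps["genetic_pos"] * 100
    bim["bp"] = snps["physical_pos"]
    bim["a1"] = snps["allele1"]
    bim["a2"] = snps["allele2"]
    bim.to_csv(tmp_path / "x.bim", sep="\t", header=False, index=False)
    (tmp_path / "x.fam").write_text("P1 i1 0 0 0 -9\nP2 i2 0 0 0 -9\n")
    G = genio.read_genotypes(tmp_path / "x", "plink")
    assert np.array_equal(G.calls, tiny_matrix.calls)
    assert np.allclose(G.snps["genetic_pos"], snps["genetic_pos"])


@pytest.mark.parametrize("fmt", ["eigenstrat", "plink"])
def test_round_trip_identity(tmp_path, rng, fmt):
    G = random_matrix(rng, n_samples=10, n_snps=1000, missing=0.08, n_pops=3)
    genio.write_genotypes(G, tmp_path / "rt", fmt)
    H = genio.read_genotypes(tmp_path / "rt", fmt)
    assert np.array_equal(G.calls, H.calls)
    assert list(G.samples["sample_id"]) == list(H.samples["sample_id"])
    assert list(G.samples["population"]) == list(H.samples["population"])
    assert list(G.snps["snp_id"]) == list(H.snps["snp_id"])
    assert np.allclose(G.snps["genetic_pos"], H.snps["genetic_pos"])
    assert list(G.snps["allele1"]) == list(H.snps["allele1"])


def test_write_refuses_empty(tmp_path, tiny_matrix):
    empty = genio.GenotypeMatrix(tiny_matrix.samples.iloc[:0], tiny_matrix.snps,
                                 np.empty((0, 3), dtype=np.int8))
    with pytest.raises(ValueError):
        genio.write_genotypes(empty, tmp_path / "e", "eigenstrat")


def test_single_call_geno_body(tmp_path):
    samples = pd.DataFrame({"sample_id": ["i"], "population": ["P"]})
    G = genio.GenotypeMatrix(samples, make_snp_table(1), np.array([[2]], dtype=np.int8))
    genio.write_genotypes(G, tmp_path / "one", "eigenstrat")
    assert (tmp_path / "one.geno").read_text().strip() == "2"


def test_dimension_mismatch_names_file(tmp_path):
    (tmp_path / "x.geno").write_text("02\n19\n")  # 2 lines for 3 SNPs
    make_snp_table(3).to_csv(tmp_path / "x.snp", sep="\t", header=False, index=False)
    (tmp_path / "x.ind").write_text("i1 U P1\ni2 U P2\n")
    with pytest.raises(genio.GenotypeFormatError, match="geno"):
        genio.read_genotypes(tmp_path / "x", "eigenstrat")


def test_unknown_symbol_reports_position(tmp_path):
    (tmp_path / "x.geno").write_text("02\n1x\n20\n")
    make_snp_table(3).to_csv(tmp_path / "x.snp", sep="\t", header=False, index=False)
    (tmp_path / "x.ind").write_text("i1 U P1\ni2 U P2\n")
    with pytest.raises(genio.GenotypeFormatError, match="line 2"):
        genio.read_genotypes(tmp_path / "x", "eigenstrat")


# ---------------------------------------------------------------------------
# filtering

def test_filter_sites_boundary_inclusive():
    """A 5% missing site is retained at the 5% threshold."""
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(20)],
                            "population": ["P"] * 20})
    calls = np.ones((20, 2), dtype=np.int8)
    calls[0, 1] = MISSING  # exactly 5% missing at SNP 2
    G = genio.GenotypeMatrix(samples, make_snp_table(2), calls)
    assert genio.filter_sites(G, 0.05).n_snps == 2
    assert genio.filter_sites(G, 0.04).n_snps == 1


def test_filter_sites_brute_force_and_idempotent(rng):
    G = random_matrix(rng, n_samples=50, n_snps=500, missing=0.06)
    H = genio.filter_sites(G, 0.05)
    expected = [j for j in range(G.n_snps)
                if sum(G.calls[i, j] == MISSING for i in range(G.n_samples)) / G.n_samples
                <= 0.05]
    assert list(H.snps.index) == list(range(len(expected)))
    assert [G.snps["snp_id"].iat[j] for j in expected] == list(H.snps["snp_id"])
    H2 = genio.filter_sites(H, 0.05)
    assert np.array_equal(H.calls, H2.calls)


# ---------------------------------------------------------------------------
# LD pruning

def _brute_force_prune(G, window, step, r2_max):
    """Literal replay of the greedy window rule with pairwise-complete r^2."""
    calls = G.calls.astype(float)
    calls[G.calls == MISSING] = np.nan

    def r2(a, b):
        ok = ~(np.isnan(calls[:, a]) | np.isnan(calls[:, b]))
        if ok.sum() < 2:
            return 0.0
        x, y = calls[ok, a], calls[ok, b]
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    keep = set(range(G.n_snps))
    chrom = G.snps["chromosome"].to_numpy()
    for c in pd.unique(chrom):
        idx = [j for j in range(G.n_snps) if chrom[j] == c]
        start = 0
        while start < len(idx):
            win = idx[start:start + window]
            for ai in range(len(win)):
                for bi in range(ai + 1, len(win)):
                    a, b = win[ai], win[bi]
                    if a in keep and b in keep and r2(a, b) > r2_max:
                        keep.discard(b)
            if start + window >= len(idx):
                break
            start += step
    return sorted(keep)


def test_prune_removes_duplicate_keeps_independent(rng):
    G = random_matrix(rng, n_samples=20, n_snps=6, missing=0.0)
    G.calls[:, 3] = G.calls[:, 2]  # perfect correlation
    H = genio.ld_prune(G, window=6, step=3, r2_max=0.5)
    kept = set(H.snps["snp_id"])
    assert ("rs2" in kept) != ("rs3" in kept) or "rs3" not in kept
    assert "rs2" in kept and "rs3" not in kept  # later-indexed SNP removed


def test_prune_matches_brute_force_window_replay(rng):
    G = random_matrix(rng, n_samples=30, n_snps=200, missing=0.02, n_chrom=2)
    # plant correlated pairs
    for j in range(0, 180, 17):
        G.calls[:, j + 1] = G.calls[:, j]
    H = genio.ld_prune(G, window=50, step=5, r2_max=0.5)
    expected = _brute_force_prune(G, 50, 5, 0.5)
    assert list(H.snps["snp_id"]) == [G.snps["snp_id"].iat[j] for j in expected]
    H2 = genio.ld_prune(H, window=50, step=5, r2_max=0.5)
    assert np.array_equal(H.calls, H2.calls)


def test_prune_window_smaller_than_step_errors(tiny_matrix):
    with pytest.raises(ValueError):
        genio.ld_prune(tiny_matrix, window=2, step=5)


# ---------------------------------------------------------------------------
# allele frequencies

def test_pop_freqs_small_cases(tiny_matrix):
    F = genio.pop_freqs(tiny_matrix)
    # P1: calls 0,1,2 -> freq 0, .5, 1 with total 2
    assert F.count1[0].tolist() == [0, 1, 2]
    assert F.total[0].tolist() == [2, 2, 2]
    # P2: missing at SNP 2 -> total 0, freq undefined
    assert F.total[1].tolist() == [2, 0, 2]
    assert np.isnan(F.freq[1, 1])


def test_pop_freqs_matches_brute_force(rng):
    G = random_matrix(rng, n_samples=30, n_snps=100, missing=0.1, n_pops=1)
    F = genio.pop_freqs(G, ["P0"])
    for j in rng.choice(100, 20, replace=False):
        obs = [c for c in G.calls[:, j] if c != MISSING]
        assert F.count1[0, j] == sum(obs)
        assert F.total[0, j] == 2 * len(obs)


def test_pop_freqs_unknown_population(tiny_matrix):
    with pytest.raises(KeyError, match="P1"):
        genio.pop_freqs(tiny_matrix, ["Nope"])


def test_pop_freqs_totals_monotone(rng):
    G = random_matrix(rng, n_samples=12, n_snps=50, missing=0.1, n_pops=1)
    sub = genio.GenotypeMatrix(G.samples.iloc[:6], G.snps, G.calls[:6])
    F_all = genio.pop_freqs(G, ["P0"])
    F_sub = genio.pop_freqs(sub, ["P0"])
    assert (F_all.total >= F_sub.total).all()
    assert (F_all.total <= 2 * 12).all()


# ---------------------------------------------------------------------------
# block assignment

def test_blocks_single_position_single_block():
    snps = make_snp_table(10, span=0.0)
    snps["genetic_pos"] = 0.01  # identical positions, no fallback
    bp = genio.assign_blocks(snps, 0.05)
    assert bp.n_blocks == 1
    assert bp.block_sizes.tolist() == [10]


def test_blocks_never_cross_chromosomes():
    snps = make_snp_table(10, n_chrom=2, span=0.0)
    snps["genetic_pos"] = 0.01
    bp = genio.assign_blocks(snps, 0.05)
    assert bp.n_blocks == 2
    for b in range(bp.n_blocks):
        assert snps["chromosome"][bp.block_of == b].nunique() == 1


def test_blocks_start_anchored_rule():
    """Positions 0, .03, .06, .09 with span .05 -> blocks {1,2} and {3,4}."""
    snps = make_snp_table(4)
    snps["genetic_pos"] = [0.0, 0.03, 0.06, 0.09]
    bp = genio.assign_blocks(snps, 0.05)
    assert bp.block_of.tolist() == [0, 0, 1, 1]


def test_blocks_concatenation_reconstructs_snps(rng):
    snps = make_snp_table(200, n_chrom=3, span=0.4)
    bp = genio.assign_blocks(snps, 0.05)
    order = np.concatenate([np.flatnonzero(bp.block_of == b) for b in range(bp.n_blocks)])
    assert order.tolist() == list(range(len(snps)))
    assert bp.block_sizes.sum() == len(snps)
    with pytest.raises(ValueError):
        genio.assign_blocks(snps, -0.1)


# ---------------------------------------------------------------------------
# merging

def test_merge_harmonizes_swapped_alleles(rng):
    G = random_matrix(rng, n_samples=4, n_snps=5, missing=0.0)
    H = random_matrix(rng, n_samples=3, n_snps=5, missing=0.0)
    H.samples["sample_id"] = ["t0", "t1", "t2"]
    H.snps = G.snps.copy()
    # swap alleles at SNP 1 (A/G -> G/A): calls must flip on merge
    H.snps.loc[1, ["allele1", "allele2"]] = ["G", "A"]
    # mismatching pair at SNP 3: dropped
    H.snps.loc[3, ["allele1", "allele2"]] = ["C", "T"]
    M = genio.merge_datasets(G, H)
    assert M.n_snps == 4 and M.n_samples == 7
    flipped = np.where(H.calls[:, 1] == MISSING, MISSING, 2 - H.calls[:, 1])
    assert np.array_equal(M.calls[4:, 1], flipped)
    assert np.array_equal(M.calls[:4], G.calls[:, [0, 1, 2, 4]])
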