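"""Sequence weighting, conservation scores, the coupling matrix and
sector extraction."""

import numpy as np
import pytest

from cxvar.sca import (
    ALPHABET,
    BACKGROUND_FREQS,
    GAP,
    SCAConfig,
    compute_weights,
    conservation_Di,
    conservation_profile,
    encode_sequences,
    extract_sectors,
    filter_alignment,
    position_frequencies,
    read_msa,
    sca_matrix,
    sector_membership,
    significant_modes,
)
from cxvar.synthetic import MSASpec, generate_msa, write_msa_fasta

AA = ALPHABET


def _wal(seqs, cfg=None, ref_id=None):
    cfg = cfg or SCAConfig(ref_identity_max=1.0)
    ids = [f"s{i}" for i in range(len(seqs))]
    return filter_alignment(ids, encode_sequences(seqs), ref_id or ids[0], cfg)


# ---------------------------------------------------------------- weights

def test_weights_identical_sequences():
    mat = encode_sequences(["ACDEF"] * 7)
    w, meff = compute_weights(mat, 0.8)
    assert np.allclose(w, 1 / 7)
    assert meff == pytest.approx(1.0)


def test_weights_mutually_dissimilar_sequences():
    mat = encode_sequences(["AAAAA", "CCCCC", "DDDDD", "EEEEE"])
    w, meff = compute_weights(mat, 0.8)
    assert np.allclose(w, 1.0)
    assert meff == pytest.approx(4.0)


def test_weights_match_bruteforce_neighbor_count(rng):
    n, L = 24, 30
    mat = rng.integers(0, 4, size=(n, L)).astype(np.int8)  # few states -> similarity
    w, meff = compute_weights(mat, 0.5)
    for s in range(n):
        count = sum(
            1 for t in range(n) if np.mean(mat[s] == mat[t]) >= 0.5
        )
        assert w[s] == pytest.approx(1.0 / count)
    assert 1.0 <= meff <= n


def test_meff_bounds_and_duplicate_insensitivity():
    # clique case: duplicating a member of an identical block keeps Meff
    base = ["ACDEFGHIKL", "ACDEFGHIKL", "WWWWWWWWWW", "YYYYYYYYYY"]
    w0, meff0 = compute_weights(encode_sequences(base), 0.8)
    w1, meff1 = compute_weights(encode_sequences(base + ["ACDEFGHIKL"]), 0.8)
    assert meff1 == pytest.approx(meff0, abs=1e-9)
    # duplicate added to a mutually dissimilar set
    solo = ["AAAAA", "CCCCC", "DDDDD"]
    _, m0 = compute_weights(encode_sequences(solo), 0.8)
    _, m1 = compute_weights(encode_sequences(solo + ["AAAAA"]), 0.8)
    assert m1 == pytest.approx(m0, abs=1e-9)
    assert m0 == pytest.approx(3.0)


# ---------------------------------------------------------------- filtering

def test_filter_drops_reference_duplicates_above_max_identity():
    # five copies of the reference: duplicates at identity 1.0 > 0.85 drop,
    # the reference itself is exempt.
    seqs = ["ACDEFGHIKL"] * 5
    wal = _wal(seqs, cfg=SCAConfig())
    assert wal.n_sequences == 1
    assert wal.ids == ["s0"]


def test_filter_drops_all_gap_sequence():
    seqs = ["ACDEFGHIKL", "----------", "ACDEFGHIKW"]
    wal = _wal(seqs, cfg=SCAConfig(ref_identity_max=0.95))
    assert "s1" not in wal.ids


def test_filter_restricts_to_reference_and_structured_columns():
    #           1234  (reference residue numbering skips its gap)
    seqs = ["AC-DE", "ACWDX", "ACFD-"]
    cfg = SCAConfig(ref_identity_max=1.0, max_gap_col=0.5)
    ids = ["r", "a", "b"]
    wal = filter_alignment(ids, encode_sequences(seqs), "r", cfg,
                           structured_positions=[1, 2, 3])
    assert wal.ref_positions.tolist() == [1, 2, 3]
    assert wal.matrix.shape == (3, 3)


def test_filter_matches_bruteforce_application(rng):
    """Fuzzed MSAs: surviving sets equal a naive sequential filter."""
    cfg = SCAConfig(ref_identity_min=0.2, ref_identity_max=0.9,
                    max_gap_seq=0.3, max_gap_col=0.3)
    for trial in range(20):
        n, L = 12, 24
        mat = rng.integers(0, 6, size=(n, L)).astype(np.int8)
        mat[rng.random((n, L)) < 0.15] = GAP
        mat[0, mat[0] == GAP] = 0  # ungapped reference
        ids = [f"s{i}" for i in range(n)]
        wal = filter_alignment(ids, mat, "s0", cfg)

        # oracle
        ref = mat[0]
        keep = []
        for i in range(n):
            gapf = np.mean(mat[i] == GAP)
            ident = np.mean(mat[i] == ref)
            ok = gapf <= 0.3 and 0.2 <= ident <= 0.9
            keep.append(ok or i == 0)
        surv = mat[np.array(keep)]
        col_ok = np.mean(surv == GAP, axis=0) <= 0.3
        assert wal.ids == [ids[i] for i in range(n) if keep[i]]
        assert np.array_equal(wal.matrix, surv[:, col_ok])


def test_filter_errors():
    with pytest.raises(ValueError, match="reference id"):
        _wal(["ACDEF"], ref_id="nope")


def test_read_msa_roundtrip(tmp_path, rng):
    spec = MSASpec(n_sequences=10, n_columns=15, conservation=0.7, gap_rate=0.1)
    ids, mat, _ = generate_msa(spec, rng)
    path = tmp_path / "m.fasta"
    write_msa_fasta(ids, mat, path)
    ids2, mat2 = read_msa(path)
    assert ids2 == ids
    assert np.array_equal(mat2, mat)


# ---------------------------------------------------------------- frequencies & Di

def test_frequencies_conserved_column_and_pseudocount_limits():
    wal = _wal(["AW", "AW", "AW"], cfg=SCAConfig(ref_identity_max=1.0))
    tiny = SCAConfig(pseudocount=1e-12, ref_identity_max=1.0)
    f = position_frequencies(wal, tiny)
    assert f[0, ALPHABET.index("A")] == pytest.approx(1.0)
    near_one = SCAConfig(pseudocount=1 - 1e-12, ref_identity_max=1.0)
    f = position_frequencies(wal, near_one)
    assert np.allclose(f, BACKGROUND_FREQS[None, :], atol=1e-9)


def test_frequencies_match_direct_weighted_count(rng):
    n, L = 30, 12
    mat = rng.integers(0, 20, size=(n, L)).astype(np.int8)
    mat[rng.random((n, L)) < 0.1] = GAP
    mat[0] = rng.integers(0, 20, size=L)
    wal = filter_alignment([f"s{i}" for i in range(n)], mat, "s0",
                           SCAConfig(ref_identity_min=0.0, ref_identity_max=1.0,
                                     max_gap_seq=1.0, max_gap_col=0.99))
    cfg = SCAConfig(pseudocount=0.03, ref_identity_max=1.0)
    f = position_frequencies(wal, cfg)
    i = 3
    w = wal.weights
    col = wal.matrix[:, i]
    meff_i = w[col != GAP].sum()
    for a in range(20):
        raw = w[col == a].sum() / meff_i
        assert f[i, a] == pytest.approx(0.97 * raw + 0.03 * BACKGROUND_FREQS[a])
    assert np.allclose(f.sum(axis=1), 1.0, atol=1e-9)


def test_di_zero_at_background_and_ln20_when_conserved():
    assert conservation_Di(BACKGROUND_FREQS) == pytest.approx(0.0, abs=1e-12)
    uniform = np.full(20, 0.05)
    f = np.zeros(20)
    f[4] = 1.0
    assert conservation_Di(f, uniform) == pytest.approx(np.log(20.0), rel=1e-12)


def test_di_decreases_when_mixed_toward_background(rng):
    for _ in range(10):
        f = rng.dirichlet(np.ones(20))
        last = conservation_Di(f)
        for t in (0.25, 0.5, 0.75, 1.0):
            cur = conservation_Di((1 - t) * f + t * BACKGROUND_FREQS)
            assert cur <= last + 1e-12
            last = cur
        assert last == pytest.approx(0.0, abs=1e-12)
    assert conservation_Di(rng.dirichlet(np.ones(20))) >= 0.0


# ---------------------------------------------------------------- coupling matrix

def _planted_wal(rng, n=300, L=40, group=(3, 7, 11), rho=0.95):
    spec = MSASpec(n_sequences=n, n_columns=L, conservation=0.6,
                   coupled_groups=((tuple(group), rho),))
    ids, mat, _ = generate_msa(spec, rng)
    return filter_alignment(ids, mat, "synthetic_ref", SCAConfig())


def test_coupling_matrix_symmetric_nonnegative_and_reconstructs(rng):
    wal = _planted_wal(rng)
    cfg = SCAConfig()
    f = position_frequencies(wal, cfg)
    Ct = sca_matrix(wal, f, cfg)
    assert np.allclose(Ct, Ct.T)
    assert Ct.min() >= 0.0
    evals, evecs = np.linalg.eigh(Ct)
    recon = (evecs * evals) @ evecs.T
    assert np.linalg.norm(Ct - recon) <= 1e-8 * np.linalg.norm(Ct)
    assert np.sum(evals) == pytest.approx(np.trace(Ct), rel=1e-10)


def test_perfectly_covarying_pair_dominates_its_rows(rng):
    wal = _planted_wal(rng, group=(5, 20), rho=1.0)
    cfg = SCAConfig()
    Ct = sca_matrix(wal, position_frequencies(wal, cfg), cfg)
    off = Ct - np.diag(np.diag(Ct))
    assert np.argmax(off[5]) == 20
    assert np.argmax(off[20]) == 5


def test_independent_columns_off_diagonal_stays_at_null_level(rng):
    """With no planted coupling the off-diagonal stays below 3x the null
    95th percentile."""
    spec = MSASpec(n_sequences=600, n_columns=30, conservation=0.6)
    ids, mat, _ = generate_msa(spec, rng)
    cfg = SCAConfig()
    wal = filter_alignment(ids, mat, "synthetic_ref", cfg)
    Ct = sca_matrix(wal, position_frequencies(wal, cfg), cfg)
    iu = np.triu_indices_from(Ct, k=1)
    # permutation null for the same alignment
    perm = wal.matrix.copy()
    for j in range(perm.shape[1]):
        perm[:, j] = perm[rng.permutation(perm.shape[0]), j]
    from dataclasses import replace

    wal_p = replace(wal, matrix=perm)
    Ct_p = sca_matrix(wal_p, position_frequencies(wal_p, cfg), cfg)
    null95 = np.quantile(Ct_p[iu], 0.95)
    assert Ct[iu].max() <= 3.0 * null95


# ---------------------------------------------------------------- modes & sectors

def test_eigenmode_bookkeeping_and_planted_group_detected(rng):
    # In a small synthetic MSA the planted block can outweigh the diffuse
    # conservation signal and claim the first eigenmode, so this test keeps
    # that mode in the analysis (include_first_mode).
    group = (3, 7, 11, 15, 19, 23, 27, 31)
    cfg = SCAConfig(include_first_mode=True)
    wal = _planted_wal(rng, n=400, L=60, group=group, rho=0.9)
    Ct = sca_matrix(wal, position_frequencies(wal, cfg), cfg)
    modes = significant_modes(Ct, wal, cfg, rng)
    assert np.all(np.diff(modes.eigenvalues) <= 1e-12)  # sorted descending
    assert modes.k_significant >= 1
    decomp = extract_sectors(modes, Ct, cfg, rng, ref_positions=wal.ref_positions)
    planted = {g + 1 for g in group}  # 1-based
    best = max(
        len(set(p.tolist()) & planted) / len(p)
        for p in decomp.ic_ref_positions
    )
    assert best >= 2 / 3  # some IC loads essentially inside the planted group


def test_extract_sectors_requires_significant_modes(rng):
    wal = _planted_wal(rng, n=50, L=10, group=(1, 2), rho=0.0)
    cfg = SCAConfig()
    Ct = sca_matrix(wal, position_frequencies(wal, cfg), cfg)
    modes = significant_modes(Ct, wal, cfg, rng)
    modes.k_significant = 0
    with pytest.raises(ValueError):
        extract_sectors(modes, Ct, cfg, rng)


def test_single_mode_yields_single_sector(rng):
    wal = _planted_wal(rng, n=300, L=40, group=(3, 7, 11, 15), rho=0.95)
    cfg = SCAConfig()
    Ct = sca_matrix(wal, position_frequencies(wal, cfg), cfg)
    modes = significant_modes(Ct, wal, cfg, rng)
    modes.k_significant = 1
    decomp = extract_sectors(modes, Ct, cfg, rng, ref_positions=wal.ref_positions)
    assert len(decomp.sectors) == 1
    assert set(decomp.sector_ref_positions[0]) == set(decomp.ic_ref_positions[0])


def test_ic_residue_sets_invariant_to_eigenvector_sign(rng):
    wal = _planted_wal(rng, n=300, L=40, group=(2, 6, 10, 14), rho=0.95)
    cfg = SCAConfig()
    Ct = sca_matrix(wal, position_frequencies(wal, cfg), cfg)
    modes = significant_modes(Ct, wal, cfg, rng)
    if modes.k_significant < 1:
        modes.k_significant = 1
    d1 = extract_sectors(modes, Ct, cfg, np.random.default_rng(0),
                         ref_positions=wal.ref_positions)
    modes.eigenvectors = -modes.eigenvectors
    d2 = extract_sectors(modes, Ct, cfg, np.random.default_rng(0),
                         ref_positions=wal.ref_positions)
    sets1 = {frozenset(p.tolist()) for p in d1.ic_ref_positions}
    sets2 = {frozenset(p.tolist()) for p in d2.ic_ref_positions}
    assert sets1 == sets2


def test_sector_membership_mapping_equals_union_lookup(rng):
    from cxvar.domains import ResidueAlignmentMap

    wal = _planted_wal(rng, n=300, L=40, group=(3, 7, 11, 15), rho=0.95)
    cfg = SCAConfig()
    Ct = sca_matrix(wal, position_frequencies(wal, cfg), cfg)
    modes = significant_modes(Ct, wal, cfg, rng)
    if modes.k_significant < 1:
        modes.k_significant = 1
    decomp = extract_sectors(modes, Ct, cfg, rng, ref_positions=wal.ref_positions)
    union = set(np.concatenate(decomp.sector_ref_positions).tolist())

    flags = sector_membership(decomp, query_length=40)
    assert {i + 1 for i in np.flatnonzero(flags)} == union

    # through an alignment map with an offset of one (query has extra N-term residue)
    q2r = np.array([0] + list(range(1, 41)))
    amap = ResidueAlignmentMap(query_to_ref=q2r, query_seq="A" * 41,
                               ref_seq="A" * 40, score=0.0)
    mapped = sector_membership(decomp, amap=amap)
    assert not mapped[0]
    assert {i for i in range(1, 41) if mapped[i]} == {p for p in union}


def test_config_validation():
    with pytest.raises(ValueError):
        SCAConfig(pseudocount=0.0)
    with pytest.raises(ValueError):
        SCAConfig(ref_identity_min=0.9, ref_identity_max=0.5)
    with pytest.raises(ValueError):
        SCAConfig(background=np.ones(20))
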