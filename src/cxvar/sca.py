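"""Positional conservation and statistical coupling analysis (SCA) of a
connexin multiple sequence alignment.

The analysis follows the classical protein-sector workflow: restrict an
MSA to the columns mapped to structured reference positions, weight
sequences by redundancy, estimate weighted amino-acid frequencies with a
small background pseudocount, score conservation per position as the
Kullback-Leibler relative entropy D_i against a database background,
build the conservation-weighted co-variation matrix, test eigenmodes
against a column-permutation null, rotate the significant modes into
independent components (ICs), pick each IC's top-loading residues, and
group ICs into sectors by their mutual coupling.

All stochastic steps (the permutation null and the ICA rotation) consume
an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "ALPHABET",
    "BACKGROUND_FREQS",
    "SCAConfig",
    "WeightedAlignment",
    "ConservationProfile",
    "SectorDecomposition",
    "read_msa",
    "encode_sequences",
    "filter_alignment",
    "compute_weights",
    "position_frequencies",
    "conservation_Di",
    "conservation_profile",
    "ModeSignificance",
    "sca_matrix",
    "significant_modes",
    "extract_sectors",
    "sector_membership",
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
GAP = 20  # code for gap / non-standard symbol
N_AA = 20

# Database amino-acid composition (A..Y in ALPHABET order), the standard
# background used for protein-sector conservation scores; normalized to 1.
_BG = np.array([
    0.073, 0.025, 0.050, 0.061, 0.042, 0.072, 0.023, 0.053, 0.064, 0.089,
    0.023, 0.043, 0.052, 0.040, 0.052, 0.073, 0.056, 0.063, 0.013, 0.033,
])
BACKGROUND_FREQS = _BG / _BG.sum()


@dataclass(frozen=True)
class SCAConfig:
    """Tunable parameters of the conservation / coupling analysis.

    ``pseudocount`` is the background-mixing fraction for frequency
    estimation; ``weight_identity_threshold`` is the fractional identity
    above which sequences down-weight each other; the reference-identity
    bounds drop sequences too dissimilar or too similar to the reference;
    the gap fractions limit gappy sequences and columns. ``n_null_trials``
    permutation trials calibrate eigenmode significance and ``ic_tail``
    is the empirical-CDF tail used to pick each IC's residues.
    """

    background: np.ndarray = field(default_factory=lambda: BACKGROUND_FREQS.copy())
    pseudocount: float = 0.03
    weight_identity_threshold: float = 0.8
    ref_identity_min: float = 0.2
    ref_identity_max: float = 0.85
    max_gap_seq: float = 0.4
    max_gap_col: float = 0.2
    n_null_trials: int = 10
    ic_tail: float = 0.05
    include_first_mode: bool = False
    ica_tol: float = 1e-8
    ica_max_iter: int = 1000

    def __post_init__(self):
        q = np.asarray(self.background, dtype=float)
        if q.shape != (N_AA,) or not np.isclose(q.sum(), 1.0):
            raise ValueError("background must be 20 frequencies summing to 1")
        if not 0.0 < self.pseudocount < 1.0:
            raise ValueError("pseudocount must lie in (0, 1)")
        if not 0.0 < self.weight_identity_threshold <= 1.0:
            raise ValueError("weight identity threshold must lie in (0, 1]")
        if not 0.0 <= self.ref_identity_min < self.ref_identity_max <= 1.0:
            raise ValueError("reference identity bounds must satisfy 0 <= min < max <= 1")


def encode_sequences(seqs) -> np.ndarray:
    """Encode aligned sequences as an int8 matrix (20 = gap/nonstandard)."""
    lut = np.full(128, GAP, dtype=np.int8)
    for aa, i in AA_INDEX.items():
        lut[ord(aa)] = i
        lut[ord(aa.lower())] = i
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    mat = lut[np.minimum(arr, 127)].reshape(len(seqs), -1)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("aligned sequences differ in length")
    return mat


def read_msa(path) -> tuple[list[str], np.ndarray]:
    """Read an aligned FASTA into (ids, int8 matrix)."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ValueError(f"no sequences in {path}")
    return ids, encode_sequences(seqs)


def _pairwise_identity(mat: np.ndarray) -> np.ndarray:
    """Fractional identity between all sequence pairs (gap-gap counts as match)."""
    n = mat.shape[0]
    ident = np.empty((n, n), dtype=float)
    for i in range(n):
        ident[i] = (mat == mat[i]).mean(axis=1)
    return ident


@dataclass
class WeightedAlignment:
    """A filtered MSA with per-sequence weights.

    ``ref_positions`` gives, for each retained column, the 1-based
    residue number in the (ungapped) reference sequence. ``weights``
    down-weight redundant sequences; their sum is the effective sequence
    count Meff.
    """

    ids: list[str]
    matrix: np.ndarray          # (n_seqs, n_cols) int8
    ref_positions: np.ndarray   # (n_cols,) int
    weights: np.ndarray         # (n_seqs,)
    mean_pairwise_identity: float

    def __post_init__(self):
        if self.matrix.shape != (len(self.ids), len(self.ref_positions)):
            raise ValueError("matrix shape inconsistent with ids / ref_positions")
        if np.any(self.weights <= 0) or np.any(self.weights > 1 + 1e-12):
            raise ValueError("weights must lie in (0, 1]")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[1]

    @property
    def meff(self) -> float:
        return float(self.weights.sum())


def compute_weights(matrix: np.ndarray, identity_threshold: float) -> tuple[np.ndarray, float]:
    """Redundancy weights: w_s = 1 / #{s': identity(s, s') >= threshold}.

    The neighbor count includes the sequence itself, so weights lie in
    (0, 1] and Meff = sum(w) lies in [1, N].
    """
    if matrix.shape[0] < 1:
        raise ValueError("empty alignment")
    ident = _pairwise_identity(matrix)
    counts = (ident >= identity_threshold).sum(axis=1)
    w = 1.0 / counts
    return w, float(w.sum())


def filter_alignment(
    ids,
    matrix: np.ndarray,
    reference_id: str,
    cfg: SCAConfig,
    structured_positions=None,
) -> WeightedAlignment:
    """Restrict and clean the MSA, then weight the surviving sequences.

    Steps, in order: (1) keep the columns where the reference is non-gap
    and (when ``structured_positions`` is given) whose reference residue
    number is in that set; (2) drop sequences whose gap fraction exceeds
    ``max_gap_seq`` or whose fractional identity to the reference falls
    outside [ref_identity_min, ref_identity_max] — the reference itself
    is always retained; (3) drop columns whose gap fraction exceeds
    ``max_gap_col``.
    """
    ids = list(ids)
    if reference_id not in ids:
        raise ValueError(f"reference id {reference_id!r} not in alignment")
    ref_row = ids.index(reference_id)
    ref = matrix[ref_row]

    nongap_cols = np.flatnonzero(ref != GAP)
    ref_pos = np.arange(1, nongap_cols.size + 1)
    if structured_positions is not None:
        keep = np.isin(ref_pos, np.asarray(list(structured_positions), dtype=int))
        nongap_cols, ref_pos = nongap_cols[keep], ref_pos[keep]
    if nongap_cols.size == 0:
        raise ValueError("no reference-mapped columns survive the restriction")
    sub = matrix[:, nongap_cols]

    gap_frac = (sub == GAP).mean(axis=1)
    ref_sub = sub[ref_row]
    ident_to_ref = (sub == ref_sub).mean(axis=1)
    keep_seq = (
        (gap_frac <= cfg.max_gap_seq)
        & (ident_to_ref >= cfg.ref_identity_min)
        & (ident_to_ref <= cfg.ref_identity_max)
    )
    keep_seq[ref_row] = True
    if not keep_seq.any():
        raise ValueError("all sequences removed by the filters")
    sub = sub[keep_seq]
    kept_ids = [i for i, k in zip(ids, keep_seq) if k]

    col_gap = (sub == GAP).mean(axis=0)
    keep_col = col_gap <= cfg.max_gap_col
    if not keep_col.any():
        raise ValueError("all columns removed by the gap filter")
    sub = sub[:, keep_col]
    ref_pos = ref_pos[keep_col]

    weights, _ = compute_weights(sub, cfg.weight_identity_threshold)
    ident = _pairwise_identity(sub)
    n = sub.shape[0]
    mean_ident = float(ident[np.triu_indices(n, k=1)].mean()) if n > 1 else 1.0
    return WeightedAlignment(
        ids=kept_ids, matrix=sub, ref_positions=ref_pos,
        weights=weights, mean_pairwise_identity=mean_ident,
    )


def _one_hot(matrix: np.ndarray) -> np.ndarray:
    """(N, L, 20) float64 one-hot; gaps are all-zero rows."""
    n, L = matrix.shape
    X = np.zeros((n, L, N_AA))
    rows, cols = np.nonzero(matrix != GAP)
    X[rows, cols, matrix[rows, cols]] = 1.0
    return X


def position_frequencies(wal: WeightedAlignment, cfg: SCAConfig) -> np.ndarray:
    """Weighted per-position amino-acid frequencies with pseudocount.

    f_i^a = (1 - lam) * sum_s w_s [x_si = a] / Meff_i + lam * q_a, where
    Meff_i sums the weights of the sequences that are not gapped at i.
    Gaps are excluded from the 20-state simplex (frequencies at each
    position renormalize over observed residues only).
    """
    X = _one_hot(wal.matrix)
    w = wal.weights
    counts = np.einsum("s,sla->la", w, X)
    meff_i = counts.sum(axis=1)
    if np.any(meff_i <= 0):
        raise ValueError("position with no non-gap residues; tighten the column gap filter")
    raw = counts / meff_i[:, None]
    lam = cfg.pseudocount
    return (1.0 - lam) * raw + lam * cfg.background[None, :]


def conservation_Di(freqs: np.ndarray, background: np.ndarray | None = None) -> np.ndarray:
    """Kullback-Leibler relative entropy per position (natural log).

    D_i = sum_a f_i^a ln(f_i^a / q_a); zero iff the position matches the
    background exactly, and ln 20 for a fully conserved residue under a
    uniform background.
    """
    q = BACKGROUND_FREQS if background is None else np.asarray(background, dtype=float)
    f = np.atleast_2d(np.asarray(freqs, dtype=float))
    if np.any(f < 0) or np.any(q <= 0):
        raise ValueError("frequencies must be non-negative and background strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(f / q[None, :]), 0.0)
    di = terms.sum(axis=1)
    return di if np.asarray(freqs).ndim > 1 else float(di[0])


@dataclass
class ConservationProfile:
    """Per-position weighted frequencies and conservation scores."""

    ref_positions: np.ndarray
    frequencies: np.ndarray   # (L, 20)
    di: np.ndarray            # (L,)
    background: np.ndarray

    @property
    def mean_di(self) -> float:
        return float(self.di.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.ref_positions, "Di": self.di})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def conservation_profile(wal: WeightedAlignment, cfg: SCAConfig) -> ConservationProfile:
    freqs = position_frequencies(wal, cfg)
    return ConservationProfile(
        ref_positions=wal.ref_positions.copy(),
        frequencies=freqs,
        di=conservation_Di(freqs, cfg.background),
        background=np.asarray(cfg.background, dtype=float),
    )


def sca_matrix(wal: WeightedAlignment, freqs: np.ndarray, cfg: SCAConfig) -> np.ndarray:
    """Conservation-weighted co-variation matrix.

    Raw pair covariances C_ij^ab = f_ij^ab - f_i^a f_j^b come from
    weighted pair counts (per-pair effective counts over sequences
    non-gapped at both positions). Each entry is weighted by the
    positional gradients phi_i^a = ln[f_i^a (1 - q_a) / ((1 - f_i^a) q_a)]
    of the binary relative entropy, and the 20x20 amino-acid block for
    each position pair is collapsed by its Frobenius norm. The diagonal
    is retained.
    """
    L = wal.n_positions
    if L < 2:
        raise ValueError("co-variation needs at least two positions")
    lam = cfg.pseudocount
    q = np.asarray(cfg.background, dtype=float)
    X = _one_hot(wal.matrix)                       # (N, L, 20)
    w = wal.weights
    Xf = (X * w[:, None, None]).reshape(wal.n_sequences, L * N_AA)
    Xu = X.reshape(wal.n_sequences, L * N_AA)
    pair_counts = Xf.T @ Xu                        # (L20, L20)
    nongap = (wal.matrix != GAP).astype(float)
    meff_pair = (nongap * w[:, None]).T @ nongap   # (L, L)
    if np.any(meff_pair <= 0):
        raise ValueError("position pair with no jointly non-gap sequences")
    raw2 = pair_counts.reshape(L, N_AA, L, N_AA) / meff_pair[:, None, :, None]
    f2 = (1.0 - lam) * raw2
    f2 += lam * np.einsum("a,b->ab", q, q)[None, :, None, :]
    C = f2 - np.einsum("ia,jb->iajb", freqs, freqs)
    phi = np.log(freqs * (1.0 - q[None, :]) / ((1.0 - freqs) * q[None, :]))
    C *= phi[:, :, None, None]
    C *= phi[None, None, :, :]
    Ct = np.sqrt(np.einsum("iajb,iajb->ij", C, C))
    return 0.5 * (Ct + Ct.T)  # symmetrize against float round-off


def _eigh_descending(Ct: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    evals, evecs = np.linalg.eigh(Ct)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


@dataclass
class ModeSignificance:
    """Spectrum of the coupling matrix against the column-permutation null."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    k_significant: int
    null_spectra: np.ndarray   # (n_trials, L)
    threshold: float
    include_first_mode: bool


def significant_modes(
    Ct: np.ndarray,
    wal: WeightedAlignment,
    cfg: SCAConfig,
    rng: np.random.Generator,
) -> ModeSignificance:
    """Count eigenmodes exceeding a column-permutation null.

    The null shuffles each column's residues independently across
    sequences (destroying inter-column correlation while preserving
    per-column composition and the sequence weights), rebuilds the
    coupling matrix, and records its spectrum; ``n_null_trials`` times.
    The significance threshold is the maximum eigenvalue observed in any
    null trial. By default the first eigenmode — dominated by overall
    conservation and shared by the null — is excluded on both sides, and
    k counts the remaining true eigenvalues above the threshold.
    """
    evals, evecs = _eigh_descending(Ct)
    L = wal.n_positions
    null_spectra = np.empty((cfg.n_null_trials, L))
    for t in range(cfg.n_null_trials):
        perm = wal.matrix.copy()
        for j in range(L):
            perm[:, j] = perm[rng.permutation(perm.shape[0]), j]
        wal_perm = replace(wal, matrix=perm)
        f_perm = position_frequencies(wal_perm, cfg)
        null_spectra[t] = _eigh_descending(sca_matrix(wal_perm, f_perm, cfg))[0]
    start = 0 if cfg.include_first_mode else 1
    threshold = float(null_spectra[:, start:].max())
    k = int(np.sum(evals[start:] > threshold))
    return ModeSignificance(
        eigenvalues=evals, eigenvectors=evecs, k_significant=k,
        null_spectra=null_spectra, threshold=threshold,
        include_first_mode=cfg.include_first_mode,
    )


@dataclass
class SectorDecomposition:
    """Independent components of the significant eigenmodes and their
    grouping into sectors.

    ``ic_positions`` are per-IC arrays of alignment-column indices;
    ``ic_ref_positions`` the same in reference residue numbering.
    ``sectors`` partitions the IC indices; each sector's residue set is
    the union of its ICs' residues.
    """

    eigenvalues: np.ndarray
    k_significant: int
    ic_loadings: np.ndarray          # (L, k)
    ic_positions: list[np.ndarray]
    ic_ref_positions: list[np.ndarray]
    sectors: list[list[int]]
    sector_ref_positions: list[np.ndarray]
    ic_coupling: np.ndarray          # (k, k) mean coupling between IC residue sets

    def to_json(self, path=None):
        payload = {
            "eigenvalues": self.eigenvalues.tolist(),
            "k_significant": self.k_significant,
            "ic_residues": [p.tolist() for p in self.ic_ref_positions],
            "sectors": [
                {"ics": [i + 1 for i in ics], "residues": sorted(res.tolist())}
                for ics, res in zip(self.sectors, self.sector_ref_positions)
            ],
        }
        if path is None:
            return payload
        import json
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _ic_rotation(V: np.ndarray, k: int, cfg: SCAConfig, rng: np.random.Generator) -> np.ndarray:
    """Fixed-point ICA (logcosh contrast) of the top-k eigenvector matrix."""
    if k == 1:
        return V[:, :1].copy()
    seed = int(rng.integers(0, 2**31 - 1))
    ica = FastICA(
        n_components=k, fun="logcosh", tol=cfg.ica_tol, max_iter=cfg.ica_max_iter,
        whiten="unit-variance", random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            S = ica.fit_transform(V)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"ICA did not converge in {cfg.ica_max_iter} iterations (seed {seed})"
            ) from exc
    return S


def extract_sectors(
    modes: ModeSignificance,
    Ct: np.ndarray,
    cfg: SCAConfig,
    rng: np.random.Generator,
    ref_positions: np.ndarray | None = None,
    n_sectors: int | None = None,
) -> SectorDecomposition:
    """Rotate significant eigenmodes into ICs and group ICs into sectors.

    Per IC, the residues in the upper ``ic_tail`` of the empirical
    loading distribution (after sign orientation) are selected. ICs are
    clustered by average linkage on their mean inter-set coupling in the
    co-variation matrix, and the dendrogram is cut at the number of
    sectors maximizing the within/between mean-coupling ratio (or at
    ``n_sectors`` when forced).
    """
    k = modes.k_significant
    if k < 1:
        raise ValueError("no significant eigenmodes; nothing to rotate")
    L = Ct.shape[0]
    start = 0 if modes.include_first_mode else 1
    V = modes.eigenvectors[:, start : start + k]
    S = _ic_rotation(V, k, cfg, rng)
    # orient each IC so its largest-magnitude loading is positive
    for j in range(S.shape[1]):
        if S[np.argmax(np.abs(S[:, j])), j] < 0:
            S[:, j] = -S[:, j]
    n_sel = max(1, int(np.ceil(cfg.ic_tail * L)))
    ic_positions = [np.sort(np.argsort(S[:, j])[-n_sel:]) for j in range(k)]

    coupling = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            ia, ib = ic_positions[a], ic_positions[b]
            block = Ct[np.ix_(ia, ib)]
            if a == b:
                off = ~np.eye(len(ia), dtype=bool)
                coupling[a, b] = block[off].mean() if len(ia) > 1 else block.mean()
            else:
                coupling[a, b] = block.mean()

    if k == 1:
        sectors = [[0]]
    else:
        dist = coupling.max() - coupling
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        if n_sectors is not None:
            labels = fcluster(Z, t=min(n_sectors, k), criterion="maxclust")
        else:
            best, labels = -np.inf, None
            for n_try in range(2, k + 1):
                lab = fcluster(Z, t=n_try, criterion="maxclust")
                within, between = [], []
                for a in range(k):
                    for b in range(a + 1, k):
                        (within if lab[a] == lab[b] else between).append(coupling[a, b])
                within.append(np.mean(np.diag(coupling)))
                score = np.mean(within) / np.mean(between) if between else -np.inf
                if score > best:
                    best, labels = score, lab
            if labels is None:
                labels = np.ones(k, dtype=int)
        sectors = [sorted(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        sectors = [list(map(int, s)) for s in sectors]
        sectors.sort(key=lambda s: s[0])

    refpos = np.arange(1, L + 1) if ref_positions is None else np.asarray(ref_positions)
    ic_ref = [refpos[p] for p in ic_positions]
    sector_ref = [
        np.unique(np.concatenate([ic_ref[i] for i in ics])) for ics in sectors
    ]
    return SectorDecomposition(
        eigenvalues=modes.eigenvalues,
        k_significant=k,
        ic_loadings=S,
        ic_positions=ic_positions,
        ic_ref_positions=ic_ref,
        sectors=sectors,
        sector_ref_positions=sector_ref,
        ic_coupling=coupling,
    )


def sector_membership(decomp: SectorDecomposition, amap=None, query_length=None) -> np.ndarray:
    """Boolean per-residue sector membership.

    Without an alignment map, returns membership over reference positions
    1..max. With a :class:`cxvar.domains.ResidueAlignmentMap`, membership
    is transferred to the query: a query residue is in a sector when its
    aligned reference residue belongs to any sector's residue set.
    """
    sector_pos = (
        set(np.concatenate(decomp.sector_ref_positions).tolist())
        if decomp.sector_ref_positions else set()
    )
    if amap is None:
        n = query_length or (max(sector_pos) if sector_pos else 0)
        out = np.zeros(int(n), dtype=bool)
        for p in sector_pos:
            if 1 <= p <= n:
                out[p - 1] = True
        return out
    out = np.zeros(len(amap.query_to_ref), dtype=bool)
    for i, rp in enumerate(amap.query_to_ref):
        if rp > 0 and int(rp) in sector_pos:
            out[i] = True
    return out
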