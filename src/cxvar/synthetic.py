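"""Synthetic alignments and variant cohorts with known ground truth.

Two generators make every pipeline stage testable without downloads:

* :func:`generate_msa` emits an exchangeable-sequence alignment with a
  stated per-column conservation level and planted co-varying residue
  groups (a two-state group-switching model: with probability equal to
  the coupling strength, all columns of a group adopt one shared state
  per sequence). This emulates a deeply sampled protein-family MSA; it
  makes no claim about phylogeny — sequences are exchangeable, without
  tree structure.

* :func:`generate_cohorts` emits disease-like and population-like
  variant tables over a segmented protein, with a per-partition odds
  multiplier controlling structured/unstructured enrichment and a
  configurable variant-type mixture, emulating curated variant lists.

All randomness flows through one injectable ``numpy.random.Generator``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .domains import STRUCTURED_LABELS, DomainSegmentation, default_segmentation
from .sca import ALPHABET, BACKGROUND_FREQS, GAP
from .variants import ONE_TO_THREE, VTYPES

__all__ = ["MSASpec", "CohortSpec", "generate_msa", "generate_cohorts", "write_fixtures"]

REFERENCE_ID = "synthetic_ref"

# Paper-like defaults for the two cohorts: disease lists are dominated by
# missense; population (gnomAD-style) lists carry a large synonymous
# fraction and a small tail of truncating / indel / start-stop events.
DISEASE_MIXTURE = {
    "missense": 0.87, "stop_gained": 0.05, "frameshift": 0.06,
    "inframe_indel": 0.015, "start_lost": 0.005,
}
POPULATION_MIXTURE = {
    "missense": 0.59, "synonymous": 0.35, "stop_gained": 0.03,
    "frameshift": 0.015, "inframe_indel": 0.01, "stop_lost": 0.003,
    "start_lost": 0.002,
}


@dataclass(frozen=True)
class MSASpec:
    """Recipe for one synthetic alignment.

    ``conservation`` is the per-column probability of the consensus
    residue (scalar or per-column array); the remaining mass is spread
    according to the background. ``coupled_groups`` plant co-variation:
    each (columns, rho) group co-switches between two group-consensus
    states with probability rho per sequence, and switches its columns
    independently otherwise.
    """

    n_sequences: int = 400
    n_columns: int = 200
    conservation: float | np.ndarray = 0.6
    coupled_groups: tuple[tuple[tuple[int, ...], float], ...] = ()
    gap_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        cols_seen: set[int] = set()
        for cols, rho in self.coupled_groups:
            if not 0.0 <= rho <= 1.0:
                raise ValueError("coupling strength must lie in [0, 1]")
            s = set(cols)
            if s & cols_seen:
                raise ValueError("coupled groups must use disjoint column sets")
            if max(s) >= self.n_columns or min(s) < 0:
                raise ValueError("coupled-group column index out of range")
            cols_seen |= s
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap rate must lie in [0, 1)")


def _conservation_array(spec: MSASpec) -> np.ndarray:
    c = np.asarray(spec.conservation, dtype=float)
    if c.ndim == 0:
        c = np.full(spec.n_columns, float(c))
    if c.shape != (spec.n_columns,) or np.any(c < 0) or np.any(c > 1):
        raise ValueError("conservation must be a scalar or per-column array in [0, 1]")
    return c


def generate_msa(spec: MSASpec, rng: np.random.Generator):
    """Draw one alignment; returns (ids, int8 matrix, ground_truth dict).

    The first row is the all-consensus reference ``synthetic_ref``.
    Ground truth records the consensus, the alternate state of each
    coupled group and the group memberships.
    """
    c = _conservation_array(spec)
    n, L = spec.n_sequences, spec.n_columns
    consensus = rng.choice(N_ALPHA, size=L, p=BACKGROUND_FREQS)
    mat = np.where(
        rng.random((n, L)) < c[None, :],
        consensus[None, :],
        rng.choice(N_ALPHA, size=(n, L), p=BACKGROUND_FREQS),
    ).astype(np.int8)

    alt_states = {}
    for cols, rho in spec.coupled_groups:
        cols = np.asarray(sorted(cols))
        # alternate residue per column, different from the consensus
        alt = np.array([
            _draw_excluding(rng, consensus[j]) for j in cols
        ], dtype=np.int8)
        alt_states[tuple(int(j) for j in cols)] = alt
        # coupled columns are clean two-state columns: with probability rho
        # the whole group shows one shared state, otherwise columns switch
        # independently; no extra background noise is layered on top.
        coherent = rng.random(n) < rho
        group_state = rng.random(n) < 0.5          # shared two-state switch
        col_state = rng.random((n, cols.size)) < 0.5
        col_state[coherent] = group_state[coherent, None]
        mat[:, cols] = np.where(col_state, alt[None, :], consensus[cols][None, :]).astype(np.int8)

    if spec.gap_rate > 0:
        mat[rng.random((n, L)) < spec.gap_rate] = GAP

    ids = [REFERENCE_ID] + [f"seq{i:05d}" for i in range(1, n)]
    mat[0] = consensus  # ungapped all-consensus reference row
    truth = {
        "consensus": "".join(ALPHABET[a] for a in consensus),
        "coupled_groups": [
            {
                "columns": sorted(int(j) for j in cols),
                "rho": float(rho),
                "alternate": "".join(ALPHABET[a] for a in alt_states[tuple(sorted(cols))]),
            }
            for cols, rho in spec.coupled_groups
        ],
        "conservation": c.tolist(),
    }
    return ids, mat, truth


N_ALPHA = len(ALPHABET)


def _draw_excluding(rng: np.random.Generator, excluded: int) -> int:
    p = BACKGROUND_FREQS.copy()
    p[excluded] = 0.0
    p /= p.sum()
    return int(rng.choice(N_ALPHA, p=p))


def write_msa_fasta(ids, matrix, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(ids, matrix):
            seq = "".join(ALPHABET[a] if a < N_ALPHA else "-" for a in row)
            fh.write(f">{sid}\n{seq}\n")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one pair of variant cohorts over a segmented protein.

    ``odds_disease`` / ``odds_population`` multiply the per-residue odds
    of drawing a structured-domain position relative to an unstructured
    one; 1.0 means density proportional to partition length only. The
    defaults mirror a disease list strongly enriched in the structured
    domains against a population list depleted there.
    """

    gene: str = "GJA3"
    segmentation: DomainSegmentation | None = None
    protein_length: int | None = None
    n_disease: int = 60
    n_population: int = 300
    odds_disease: float = 6.0
    odds_population: float = 1.0 / 3.0
    disease_mixture: dict = field(default_factory=lambda: dict(DISEASE_MIXTURE))
    population_mixture: dict = field(default_factory=lambda: dict(POPULATION_MIXTURE))

    def __post_init__(self):
        if self.odds_disease <= 0 or self.odds_population <= 0:
            raise ValueError("odds multipliers must be positive")
        for mix in (self.disease_mixture, self.population_mixture):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("variant-type mixture must sum to 1")
            unknown = set(mix) - set(VTYPES)
            if unknown:
                raise ValueError(f"unknown variant types in mixture: {unknown}")

    def resolved_segmentation(self) -> DomainSegmentation:
        if self.segmentation is not None:
            return self.segmentation
        return default_segmentation()


def _position_probs(labels: np.ndarray, odds: float) -> np.ndarray:
    structured = np.isin(labels, list(STRUCTURED_LABELS))
    w = np.where(structured, odds, 1.0).astype(float)
    return w / w.sum()


def _hgvs_label(vtype, pos, ref, alt) -> str:
    r3 = ONE_TO_THREE[ref]
    if vtype == "missense" or vtype == "synonymous":
        return f"p.{r3}{pos}{ONE_TO_THREE[alt]}"
    if vtype == "stop_gained":
        return f"p.{r3}{pos}Ter"
    if vtype == "frameshift":
        return f"p.{r3}{pos}fs"
    if vtype == "inframe_indel":
        return f"p.{r3}{pos}del"
    if vtype == "start_lost":
        return "p.Met1?"
    if vtype == "stop_lost":
        return f"p.Ter{pos}Leu"
    raise ValueError(vtype)


def _generate_cohort(
    rng, gene, cohort, n, mixture, labels, sequence, odds, stop_position
) -> pd.DataFrame:
    probs = _position_probs(labels, odds)
    vtypes = list(mixture)
    vprobs = np.array([mixture[v] for v in vtypes])
    L = len(labels)
    rows, seen = [], set()
    attempts = 0
    max_attempts = 200 * n + 1000
    if n > L * 19:
        raise ValueError(f"cannot draw {n} unique variants over {L} positions")
    while len(rows) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("rejection sampling failed to reach the requested cohort size")
        vtype = vtypes[int(rng.choice(len(vtypes), p=vprobs))]
        if vtype == "start_lost":
            pos, ref, alt = 1, "M", None
        elif vtype == "stop_lost":
            pos, ref, alt = stop_position, None, "L"
        else:
            pos = int(rng.choice(L, p=probs)) + 1
            if vtype == "missense" and pos == 1:
                continue  # a substituted initiator Met is start-lost, not missense
            ref = sequence[pos - 1]
            if vtype == "missense":
                alt = ALPHABET[_draw_uniform_excluding(rng, ref)]
            elif vtype == "synonymous":
                alt = ref
            else:
                alt = None
        label = _hgvs_label(vtype, pos, ref if ref else "M", alt)
        if label in seen:
            continue
        seen.add(label)
        rows.append({"gene": gene, "cohort": cohort, "hgvs_p": label,
                     "position": pos, "vtype": vtype})
    return pd.DataFrame(rows)


def _draw_uniform_excluding(rng, ref_letter: str) -> int:
    k = int(rng.integers(0, N_ALPHA - 1))
    ref_idx = ALPHABET.index(ref_letter)
    return k + 1 if k >= ref_idx else k


def generate_cohorts(spec: CohortSpec, rng: np.random.Generator):
    """Draw the disease and population cohorts plus ground truth.

    Returns (disease_df, population_df, truth) where the frames carry
    gene, cohort, hgvs_p, position and vtype columns, and truth records
    the protein sequence and the partition odds actually used.
    """
    seg = spec.resolved_segmentation()
    L = spec.protein_length or seg.reference_length
    labels = seg.labels_array()[:L]
    seq = ["M"] + [ALPHABET[i] for i in rng.choice(N_ALPHA, size=L - 1, p=BACKGROUND_FREQS)]
    sequence = "".join(seq)
    disease = _generate_cohort(
        rng, spec.gene, "disease", spec.n_disease, spec.disease_mixture,
        labels, sequence, spec.odds_disease, stop_position=L + 1,
    )
    population = _generate_cohort(
        rng, spec.gene, "population", spec.n_population, spec.population_mixture,
        labels, sequence, spec.odds_population, stop_position=L + 1,
    )
    truth = {
        "gene": spec.gene,
        "sequence": sequence,
        "odds_disease": spec.odds_disease,
        "odds_population": spec.odds_population,
        "structured_length": int(np.isin(labels, list(STRUCTURED_LABELS)).sum()),
        "unstructured_length": int(L - np.isin(labels, list(STRUCTURED_LABELS)).sum()),
    }
    return disease, population, truth


def write_fixtures(out_dir, seed: int = 0) -> dict:
    """Write a small reproducible fixture bundle (FASTA, TSVs, JSON).

    Re-running with the same seed reproduces byte-identical files; the
    manifest records the seed and a checksum per file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    msa_spec = MSASpec(
        n_sequences=120, n_columns=80, conservation=0.6,
        coupled_groups=(((5, 9, 14, 22, 30, 41), 0.9), ((50, 55, 61, 70, 77), 0.9)),
        gap_rate=0.02, seed=seed,
    )
    ids, mat, msa_truth = generate_msa(msa_spec, rng)
    write_msa_fasta(ids, mat, out / "msa.fasta")

    cohort_spec = CohortSpec()
    disease, population, cohort_truth = generate_cohorts(cohort_spec, rng)
    disease.to_csv(out / "disease_variants.tsv", sep="\t", index=False)
    population.to_csv(out / "population_variants.tsv", sep="\t", index=False)
    with open(out / "protein.fasta", "w") as fh:
        fh.write(f">{cohort_truth['gene']}\n{cohort_truth['sequence']}\n")
    cohort_spec.resolved_segmentation().to_json(out / "segmentation.json")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({"msa": msa_truth, "cohorts": cohort_truth, "seed": seed}, fh, indent=2)

    manifest = {"seed": seed, "files": {}}
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json":
            continue
        manifest["files"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
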