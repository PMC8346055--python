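"""Structure-referenced domain mapping of connexin residues and variants.

A connexin monomer has nine topological segments: the amino terminus
(NT), four transmembrane helices (M1-M4), two extracellular loops
(E1, E2), the cytoplasmic loop (CL) and the carboxyl terminus (CT).
In the cryo-EM gap-junction structure used as reference, NT, M1, E1,
M2, M3, E2 and M4 are resolved ("structured"); CL and CT are not
("unstructured"). Within the structured part, NT+M1+E1+M2 line the
channel pore and M3+E2+M4 face away from it.

A query connexin is mapped onto the reference segmentation through a
pairwise global protein alignment, after which each query residue
inherits a segment label and its partition flags; missense variants are
then located by residue position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .variants import VariantRecord

__all__ = [
    "DomainSegmentation",
    "ResidueAlignmentMap",
    "DomainMap",
    "STRUCTURED_LABELS",
    "PORE_LABELS",
    "NONPORE_LABELS",
    "UNSTRUCTURED_LABELS",
    "default_segmentation",
    "align_query_to_reference",
    "build_domain_map",
    "locate_variants",
    "region_identity",
    "read_fasta",
    "write_residue_annotation",
    "write_bfactor_attributes",
]

SEGMENT_LABELS = ("NT", "M1", "E1", "CL", "M2", "M3", "E2", "M4", "CT")
STRUCTURED_LABELS = frozenset({"NT", "M1", "E1", "M2", "M3", "E2", "M4"})
PORE_LABELS = frozenset({"NT", "M1", "E1", "M2"})
NONPORE_LABELS = frozenset({"M3", "E2", "M4"})
UNSTRUCTURED_LABELS = frozenset({"CL", "CT"})


@dataclass(frozen=True)
class DomainSegmentation:
    """Ordered, contiguous segmentation of the reference protein.

    ``segments`` is a tuple of (label, start, end) with 1-based inclusive
    bounds covering 1..reference_length without gaps or overlaps.
    """

    segments: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        if not self.segments:
            raise ValueError("empty segmentation")
        expected_start = 1
        for label, start, end in self.segments:
            if label not in SEGMENT_LABELS:
                raise ValueError(f"unknown segment label {label!r}")
            if start != expected_start:
                raise ValueError(
                    f"segment {label} starts at {start}, expected {expected_start} "
                    "(segments must be contiguous from residue 1)"
                )
            if end < start:
                raise ValueError(f"segment {label} has end {end} < start {start}")
            expected_start = end + 1

    @property
    def reference_length(self) -> int:
        return self.segments[-1][2]

    def label_of(self, ref_pos: int) -> str:
        if not 1 <= ref_pos <= self.reference_length:
            raise ValueError(f"reference position {ref_pos} outside 1..{self.reference_length}")
        for label, start, end in self.segments:
            if start <= ref_pos <= end:
                return label
        raise AssertionError("unreachable: contiguous segmentation")

    def labels_array(self) -> np.ndarray:
        """Per-residue label for reference positions 1..L (index 0 = residue 1)."""
        out = np.empty(self.reference_length, dtype=object)
        for label, start, end in self.segments:
            out[start - 1 : end] = label
        return out

    def structured_positions(self) -> np.ndarray:
        """Sorted 1-based reference positions in structured segments."""
        labels = self.labels_array()
        return np.flatnonzero(np.isin(labels, list(STRUCTURED_LABELS))) + 1

    @classmethod
    def from_json(cls, path) -> "DomainSegmentation":
        with open(path) as fh:
            data = json.load(fh)
        return cls(tuple((s["label"], int(s["start"]), int(s["end"])) for s in data["segments"]))

    @classmethod
    def from_tsv(cls, path) -> "DomainSegmentation":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(zip(df["label"], df["start"].astype(int), df["end"].astype(int))))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"segments": [{"label": l, "start": s, "end": e} for l, s, e in self.segments]},
                fh, indent=2,
            )


def default_segmentation() -> DomainSegmentation:
    """Segmentation of sheep Cx46 shipped with the package.

    Boundaries follow the resolved/unresolved ranges of the reference
    cryo-EM gap-junction model and standard connexin topology; they are
    data, not code, and can be overridden with any JSON/TSV config.
    """
    ref = resources.files("cxvar.data").joinpath("cx46_reference_segments.json")
    with resources.as_file(ref) as path:
        return DomainSegmentation.from_json(path)


@dataclass
class ResidueAlignmentMap:
    """Colinear query->reference residue map from one pairwise alignment.

    ``query_to_ref[i]`` is the 1-based reference residue aligned to query
    residue i+1, or 0 when the query residue is aligned to a gap. Mapped
    positions are strictly increasing (colinearity is enforced).
    """

    query_to_ref: np.ndarray  # int array, length = query length
    query_seq: str
    ref_seq: str
    score: float

    def __post_init__(self):
        self.query_to_ref = np.asarray(self.query_to_ref, dtype=int)
        if len(self.query_to_ref) != len(self.query_seq):
            raise ValueError("map length differs from query length")
        mapped = self.query_to_ref[self.query_to_ref > 0]
        if np.any(np.diff(mapped) <= 0):
            raise ValueError("query->reference map is not colinear")
        if mapped.size and mapped.max() > len(self.ref_seq):
            raise ValueError("map points past the reference end")

    @property
    def n_aligned_columns(self) -> int:
        """Alignment columns excluding double gaps (= matches + mismatches + indel columns)."""
        n_mapped = int(np.sum(self.query_to_ref > 0))
        q_gaps = len(self.query_seq) - n_mapped  # query residues vs gap
        r_gaps = len(self.ref_seq) - n_mapped    # reference residues vs gap
        return n_mapped + q_gaps + r_gaps

    def identity(self, ref_mask: Iterable[int] | None = None) -> float:
        """Percent identity = matches / aligned columns (no double gaps).

        With ``ref_mask`` (a set of 1-based reference positions) only
        alignment columns whose reference residue is in the mask count.
        """
        if ref_mask is None:
            matches = sum(
                1 for i, rp in enumerate(self.query_to_ref)
                if rp > 0 and self.query_seq[i] == self.ref_seq[rp - 1]
            )
            return 100.0 * matches / self.n_aligned_columns
        mask = set(int(p) for p in ref_mask)
        if not mask:
            raise ValueError("empty reference mask")
        mapped_ref = set(int(rp) for rp in self.query_to_ref if rp > 0)
        matches = cols = 0
        for i, rp in enumerate(self.query_to_ref):
            if rp > 0 and rp in mask:
                cols += 1
                if self.query_seq[i] == self.ref_seq[rp - 1]:
                    matches += 1
        # reference residues in the mask aligned to a query gap still count as columns
        cols += len(mask & set(range(1, len(self.ref_seq) + 1)) - mapped_ref)
        if cols == 0:
            raise ValueError("reference mask covers no aligned columns")
        return 100.0 * matches / cols


def align_query_to_reference(
    query_seq: str,
    ref_seq: str,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> ResidueAlignmentMap:
    """Global pairwise protein alignment with affine gaps.

    Returns the residue-level query->reference map of the best-scoring
    alignment. End gaps are penalized like internal gaps (true global
    alignment), which is appropriate at the 40-95% identity typical of
    connexin orthologs.
    """
    if not query_seq or not ref_seq:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(query_seq.upper(), ref_seq.upper())[0]
    q2r = np.zeros(len(query_seq), dtype=int)
    for (qs, qe), (rs, re_) in zip(*aln.aligned):
        q2r[qs:qe] = np.arange(rs + 1, re_ + 1)
    return ResidueAlignmentMap(
        query_to_ref=q2r, query_seq=query_seq.upper(), ref_seq=ref_seq.upper(),
        score=float(aln.score),
    )


def map_from_aligned_pair(query_row: str, ref_row: str) -> ResidueAlignmentMap:
    """Build a ResidueAlignmentMap from a precomputed pairwise alignment
    (two equal-length gapped rows, query first)."""
    if len(query_row) != len(ref_row):
        raise ValueError("aligned rows differ in length")
    q2r, qpos, rpos = [], 0, 0
    for qc, rc in zip(query_row, ref_row):
        qgap, rgap = qc in "-.", rc in "-."
        if not rgap:
            rpos += 1
        if not qgap:
            qpos += 1
            q2r.append(0 if rgap else rpos)
    return ResidueAlignmentMap(
        query_to_ref=np.array(q2r, dtype=int),
        query_seq=query_row.replace("-", "").replace(".", "").upper(),
        ref_seq=ref_row.replace("-", "").replace(".", "").upper(),
        score=float("nan"),
    )


@dataclass
class DomainMap:
    """Per-residue domain labels and partition flags for one query protein."""

    labels: np.ndarray        # object array of segment labels, length = query length
    query_seq: str
    amap: ResidueAlignmentMap | None = None

    def __post_init__(self):
        if len(self.labels) != len(self.query_seq):
            raise ValueError("label array length differs from query length")
        unknown = set(self.labels) - set(SEGMENT_LABELS)
        if unknown:
            raise ValueError(f"unknown labels {unknown}")

    @property
    def length(self) -> int:
        return len(self.labels)

    @property
    def structured(self) -> np.ndarray:
        return np.isin(self.labels, list(STRUCTURED_LABELS))

    @property
    def pore(self) -> np.ndarray:
        """True for pore residues; only meaningful where ``structured``."""
        return np.isin(self.labels, list(PORE_LABELS))

    def domain_lengths(self) -> dict[str, int]:
        out = {label: int(np.sum(self.labels == label)) for label in SEGMENT_LABELS}
        return {k: v for k, v in out.items() if v > 0}

    def partition_lengths(self) -> dict[str, int]:
        structured = int(self.structured.sum())
        return {
            "structured": structured,
            "unstructured": self.length - structured,
            "pore": int((self.structured & self.pore).sum()),
            "nonpore": int((self.structured & ~self.pore).sum()),
            "CL": int(np.sum(self.labels == "CL")),
            "CT": int(np.sum(self.labels == "CT")),
        }

    def label_of(self, position: int) -> str:
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside 1..{self.length}")
        return str(self.labels[position - 1])


def build_domain_map(amap: ResidueAlignmentMap, seg: DomainSegmentation) -> DomainMap:
    """Transfer the reference segmentation onto the query through the map.

    Mapped query residues inherit the label of their aligned reference
    residue. Gap-aligned query residues take the shared label of the two
    flanking mapped residues when those agree, otherwise the label of the
    nearest preceding mapped residue; residues before the first mapped
    position are NT, residues after the last are CT by the preceding-
    residue rule (the reference ends in CT).
    """
    if seg.reference_length < len(amap.ref_seq):
        raise ValueError(
            f"segmentation covers {seg.reference_length} residues but the reference "
            f"has {len(amap.ref_seq)}"
        )
    n = len(amap.query_to_ref)
    labels = np.empty(n, dtype=object)
    mapped_idx = np.flatnonzero(amap.query_to_ref > 0)
    if mapped_idx.size == 0:
        raise ValueError("alignment maps no query residue to the reference")
    for i in range(n):
        rp = amap.query_to_ref[i]
        if rp > 0:
            labels[i] = seg.label_of(int(rp))
    # fill gap-aligned residues
    for i in range(n):
        if labels[i] is not None:
            continue
        prev_idx = mapped_idx[mapped_idx < i]
        next_idx = mapped_idx[mapped_idx > i]
        if prev_idx.size == 0:
            labels[i] = "NT"
        elif next_idx.size == 0:
            labels[i] = labels[prev_idx[-1]]
        else:
            lp, ln = labels[prev_idx[-1]], labels[next_idx[0]]
            labels[i] = lp if lp == ln else lp
    return DomainMap(labels=labels, query_seq=amap.query_seq, amap=amap)


def locate_variants(
    missense: Sequence[VariantRecord], dmap: DomainMap
) -> pd.DataFrame:
    """Annotate missense variants with domain label and partition flags.

    Returns a DataFrame with one row per variant (gene, cohort, label,
    position, domain, structured, pore); ``pore`` is pd.NA for
    unstructured residues.
    """
    rows = []
    for r in missense:
        if r.vtype != "missense":
            raise ValueError(f"non-missense record {r.raw_label!r} passed to locate_variants")
        if r.position > dmap.length:
            raise ValueError(
                f"variant {r.raw_label!r} position {r.position} exceeds protein length {dmap.length}"
            )
        label = dmap.label_of(r.position)
        structured = label in STRUCTURED_LABELS
        rows.append(
            {
                "gene": r.gene,
                "cohort": r.cohort,
                "hgvs_p": r.raw_label,
                "position": r.position,
                "ref_aa": r.ref_aa,
                "alt_aa": r.alt_aa,
                "domain": label,
                "structured": structured,
                "pore": (label in PORE_LABELS) if structured else pd.NA,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "cohort", "hgvs_p", "position", "ref_aa", "alt_aa",
                 "domain", "structured", "pore"],
    )
    return df


def count_by_partition(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort counts in each domain and partition."""
    out = {}
    for cohort, grp in annotated.groupby("cohort"):
        counts = {f"domain_{d}": int((grp["domain"] == d).sum())
                  for d in SEGMENT_LABELS if (grp["domain"] == d).any()}
        counts["structured"] = int(grp["structured"].sum())
        counts["unstructured"] = int((~grp["structured"]).sum())
        counts["pore"] = int((grp["pore"] == True).sum())  # noqa: E712 (NA-safe)
        counts["nonpore"] = int((grp["pore"] == False).sum())  # noqa: E712
        out[cohort] = counts
    return pd.DataFrame(out).fillna(0).astype(int)


def region_identity(amap: ResidueAlignmentMap, ref_positions: Iterable[int]) -> float:
    """Percent identity over alignment columns whose reference residue lies
    in ``ref_positions`` (e.g. the structured segments)."""
    return amap.identity(ref_mask=ref_positions)


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero (display convention)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_residue_annotation(dmap: DomainMap, path) -> None:
    """Write per-residue TSV: residue, aa, domain, structured, pore."""
    structured = dmap.structured
    pore = dmap.pore
    df = pd.DataFrame(
        {
            "residue": np.arange(1, dmap.length + 1),
            "aa": list(dmap.query_seq),
            "domain": dmap.labels,
            "structured": structured,
            "pore": [bool(p) if s else "" for s, p in zip(structured, pore)],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_bfactor_attributes(pdb_in, pdb_out, values: dict[int, float], chains=None) -> None:
    """Write per-residue numeric codes into the B-factor column of a PDB file.

    ``values`` maps residue sequence numbers to the value to store;
    residues not listed get 0. Useful for coloring domains, variant
    counts or sector membership in any molecular viewer.
    """
    import gemmi

    structure = gemmi.read_pdb(str(pdb_in))
    for model in structure:
        for chain in model:
            if chains is not None and chain.name not in chains:
                continue
            for residue in chain:
                val = float(values.get(residue.seqid.num, 0.0))
                for atom in residue:
                    atom.b_iso = val
    structure.write_pdb(str(pdb_out))
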