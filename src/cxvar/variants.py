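"""Parsing, typing and cross-tabulation of protein-level variant records.

Variants arrive as HGVS p. labels (``p.Asn220Asp``) or short one-letter
forms (``N220D``, ``W4*``, ``S251fs``). Records are typed into the seven
coding-variant classes (missense, synonymous, stop gained/lost, start
lost, frameshift, in-frame indel), deduplicated per (gene, cohort,
normalized label), and compared between a disease-linked and a
population (gnomAD-style) cohort.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "TypeTabulation",
    "OverlapReport",
    "ParseError",
    "ValidationError",
    "parse_variant_label",
    "tabulate_variant_types",
    "select_missense",
    "compute_overlap",
    "read_variant_table",
    "write_variant_table",
    "VTYPES",
]

VTYPES = (
    "missense",
    "synonymous",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift",
    "inframe_indel",
)

COHORTS = ("disease", "population")

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class ParseError(ValueError):
    """Raised when a variant label does not match the supported grammar."""


class ValidationError(ValueError):
    """Raised when a parsed label violates a record invariant."""


@dataclass(frozen=True)
class VariantRecord:
    gene: str
    cohort: str
    raw_label: str
    position: int
    vtype: str
    ref_aa: str | None = None
    alt_aa: str | None = None
    multi_residue: bool = False
    allele_frequency: float | None = None
    source: str | None = None

    def __post_init__(self):
        if self.cohort not in COHORTS:
            raise ValidationError(f"unknown cohort {self.cohort!r}")
        if self.vtype not in VTYPES:
            raise ValidationError(f"unknown variant type {self.vtype!r}")
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.vtype == "missense":
            if self.ref_aa == self.alt_aa:
                raise ValidationError("missense variant with identical residues")
            for aa in (self.ref_aa, self.alt_aa):
                if aa not in STANDARD_AA:
                    raise ValidationError(f"non-standard amino acid {aa!r}")
        if self.vtype == "synonymous" and self.ref_aa != self.alt_aa:
            raise ValidationError("synonymous variant with differing residues")
        if self.allele_frequency is not None and not (0.0 <= self.allele_frequency <= 1.0):
            raise ValidationError("allele frequency outside [0, 1]")

    @property
    def key(self) -> tuple[str, str, str]:
        """Deduplication key: (gene, cohort, normalized label)."""
        return (self.gene, self.cohort, self.normalized_label)

    @property
    def normalized_label(self) -> str:
        ref = self.ref_aa or ""
        alt = self.alt_aa or ""
        if self.vtype == "frameshift":
            return f"{ref}{self.position}fs"
        if self.vtype == "inframe_indel":
            # raw label retained (ranges differ); strip p. prefix only
            return _strip_prefix(self.raw_label)
        if self.vtype == "start_lost":
            return "M1?"
        return f"{ref}{self.position}{alt}"


_AA_TOKEN = r"(?:[A-Z][a-z]{2}|[A-Z*])"
_RE_SUB = re.compile(rf"^({_AA_TOKEN})(\d+)({_AA_TOKEN}|\?|=)$")
_RE_FS = re.compile(rf"^({_AA_TOKEN})(\d+)({_AA_TOKEN})?fs(?:{_AA_TOKEN}?\d+)?$")
_RE_INDEL = re.compile(
    rf"^({_AA_TOKEN})(\d+)(?:_({_AA_TOKEN})(\d+))?(del|dup|ins|delins)([A-Za-z]*)$"
)


def _strip_prefix(raw: str) -> str:
    label = raw.strip()
    if label.lower().startswith("p."):
        label = label[2:]
    if label.startswith("(") and label.endswith(")"):
        label = label[1:-1]
    return label


def _normalize_aa(token: str, raw: str) -> str:
    """Return a one-letter code ('*' allowed) from a one- or three-letter token."""
    if len(token) == 3:
        if token not in THREE_TO_ONE:
            raise ValidationError(f"non-standard amino-acid code {token!r} in {raw!r}")
        return THREE_TO_ONE[token]
    if token == "*":
        return "*"
    if token in STANDARD_AA:
        return token
    raise ValidationError(f"non-standard amino-acid code {token!r} in {raw!r}")


def parse_variant_label(
    raw_label: str,
    gene: str,
    cohort: str,
    allele_frequency: float | None = None,
    source: str | None = None,
) -> VariantRecord:
    """Parse one HGVS p. (or short-form) protein variant label.

    Typing follows the substitution pattern: aa->different aa is missense,
    aa->same aa (or '=') synonymous, aa->* stop gained, *->aa stop lost,
    a disrupted initiator Met start lost, an ``fs`` suffix frameshift and
    del/ins/dup without fs an in-frame indel. Nucleotide-level, intronic
    and UTR notations are rejected.
    """
    label = _strip_prefix(raw_label)
    if not label:
        raise ParseError(f"empty variant label {raw_label!r}")
    common = dict(gene=gene, cohort=cohort, raw_label=raw_label,
                  allele_frequency=allele_frequency, source=source)

    m = _RE_FS.match(label)
    if m:
        ref = _normalize_aa(m.group(1), raw_label)
        return VariantRecord(position=int(m.group(2)), vtype="frameshift",
                             ref_aa=ref if ref != "*" else None, **common)

    m = _RE_INDEL.match(label)
    if m:
        ref = _normalize_aa(m.group(1), raw_label)
        multi = m.group(3) is not None or m.group(5) in ("ins", "delins")
        return VariantRecord(position=int(m.group(2)), vtype="inframe_indel",
                             ref_aa=ref if ref != "*" else None,
                             multi_residue=multi, **common)

    m = _RE_SUB.match(label)
    if m:
        ref = _normalize_aa(m.group(1), raw_label)
        pos = int(m.group(2))
        alt_token = m.group(3)
        if alt_token == "=":
            alt = ref
        elif alt_token == "?":
            alt = None
        elif alt_token == "X" and ref == "*":
            alt = None  # stop lost with unspecified new residue
        else:
            alt = _normalize_aa(alt_token, raw_label)
        if ref == "*":
            return VariantRecord(position=pos, vtype="stop_lost",
                                 ref_aa=None, alt_aa=alt, **common)
        if alt == "*":
            return VariantRecord(position=pos, vtype="stop_gained",
                                 ref_aa=ref, alt_aa="*", **common)
        if alt is None or (pos == 1 and ref == "M" and alt != "M"):
            if pos != 1 or ref != "M":
                raise ParseError(f"'?' substitution outside the initiator Met: {raw_label!r}")
            return VariantRecord(position=1, vtype="start_lost",
                                 ref_aa="M", alt_aa=alt, **common)
        vtype = "synonymous" if ref == alt else "missense"
        return VariantRecord(position=pos, vtype=vtype, ref_aa=ref, alt_aa=alt, **common)

    raise ParseError(f"unsupported variant label {raw_label!r} (token {label!r})")


def deduplicate(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Drop repeated records, keeping first occurrence per (gene, cohort, label)."""
    seen: set[tuple] = set()
    out = []
    for r in records:
        if r.key not in seen:
            seen.add(r.key)
            out.append(r)
    return out


@dataclass
class TypeTabulation:
    """Unique-variant counts and percentages by type, per gene and pooled."""

    counts: pd.DataFrame       # index: gene (+ 'pooled'); columns: vtype
    percentages: pd.DataFrame  # same shape; rows sum to 100 (or 0 when empty)

    def to_tsv(self, path) -> None:
        joined = self.counts.join(self.percentages, lsuffix="_n", rsuffix="_pct")
        joined.to_csv(path, sep="\t", index_label="gene")

    def to_json(self, path=None):
        payload = {
            "counts": {g: row.to_dict() for g, row in self.counts.iterrows()},
            "percentages": {g: row.to_dict() for g, row in self.percentages.iterrows()},
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def tabulate_variant_types(
    records: Sequence[VariantRecord], drop_synonymous: bool = False
) -> TypeTabulation:
    """Count unique variants by type, per gene and pooled.

    With ``drop_synonymous`` the synonymous records are removed before
    percentages are computed, so percentages refer to the reduced total.
    """
    records = deduplicate(records)
    if drop_synonymous:
        records = [r for r in records if r.vtype != "synonymous"]
    genes = sorted({r.gene for r in records})
    rows = {}
    for gene in genes:
        rows[gene] = Counter(r.vtype for r in records if r.gene == gene)
    rows["pooled"] = Counter(r.vtype for r in records)
    counts = pd.DataFrame(
        [[rows[g].get(v, 0) for v in VTYPES] for g in [*genes, "pooled"]],
        index=[*genes, "pooled"], columns=list(VTYPES), dtype=int,
    )
    totals = counts.sum(axis=1)
    pct = counts.div(totals.where(totals > 0, 1), axis=0) * 100.0
    pct[totals == 0] = 0.0
    return TypeTabulation(counts=counts, percentages=pct)


def select_missense(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Missense-only subset, input order preserved."""
    return [r for r in records if r.vtype == "missense"]


@dataclass
class OverlapReport:
    """Positional overlap between disease and population missense cohorts."""

    shared_positions: set  # {(gene, position)}
    disease_variants_at_shared: int
    population_variants_at_shared: int
    identical_substitutions: int

    def __post_init__(self):
        if self.identical_substitutions > min(
            self.disease_variants_at_shared, self.population_variants_at_shared
        ):
            raise ValidationError(
                "identical substitutions exceed variants at shared positions"
            )

    def to_json(self, path=None):
        payload = {
            "shared_positions": sorted(list(self.shared_positions)),
            "n_shared_positions": len(self.shared_positions),
            "disease_variants_at_shared": self.disease_variants_at_shared,
            "population_variants_at_shared": self.population_variants_at_shared,
            "identical_substitutions": self.identical_substitutions,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def compute_overlap(
    disease_missense: Sequence[VariantRecord],
    population_missense: Sequence[VariantRecord],
) -> OverlapReport:
    """Residue positions mutated in both cohorts and identical substitutions.

    Positions are keyed by (gene, position) so multi-gene inputs cannot
    collide across genes.
    """
    for recs, expected in ((disease_missense, "disease"), (population_missense, "population")):
        for r in recs:
            if r.vtype != "missense":
                raise ValidationError(f"non-missense record {r.raw_label!r} in overlap input")
    d_pos = {(r.gene, r.position) for r in disease_missense}
    p_pos = {(r.gene, r.position) for r in population_missense}
    shared = d_pos & p_pos
    d_at = [r for r in disease_missense if (r.gene, r.position) in shared]
    p_at = [r for r in population_missense if (r.gene, r.position) in shared]
    p_subs = {(r.gene, r.position, r.ref_aa, r.alt_aa) for r in population_missense}
    identical = sum(
        1 for r in disease_missense if (r.gene, r.position, r.ref_aa, r.alt_aa) in p_subs
    )
    return OverlapReport(
        shared_positions=shared,
        disease_variants_at_shared=len(d_at),
        population_variants_at_shared=len(p_at),
        identical_substitutions=identical,
    )


def read_variant_table(path) -> list[VariantRecord]:
    """Read a variant TSV (columns: gene, cohort, hgvs_p[, allele_frequency, source])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "cohort", "hgvs_p"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"variant table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        af = row.get("allele_frequency")
        af = None if af is None or pd.isna(af) else float(af)
        src = row.get("source")
        src = None if src is None or (isinstance(src, float) and pd.isna(src)) else src
        records.append(
            parse_variant_label(row["hgvs_p"], gene=row["gene"], cohort=row["cohort"],
                                allele_frequency=af, source=src)
        )
    return deduplicate(records)


def write_variant_table(records: Sequence[VariantRecord], path) -> None:
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "cohort": [r.cohort for r in records],
            "hgvs_p": [r.raw_label for r in records],
            "position": [r.position for r in records],
            "ref_aa": [r.ref_aa for r in records],
            "alt_aa": [r.alt_aa for r in records],
            "vtype": [r.vtype for r in records],
            "allele_frequency": [r.allele_frequency for r in records],
            "source": [r.source for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
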