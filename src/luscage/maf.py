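"""Somatic mutation (MAF) parsing and the three-step exclusion filter.

Tumor cohorts sequenced across multiple aliquots of the same patient yield
near-identical mutation lists per aliquot; mutations annotated to several
paralogous genes cannot be assigned to one locus; and calls inside low-complexity
(tandem-repeat) reference context are enriched for alignment artefacts. The
filter chain here removes, in order:

1. per-patient duplicates — one record kept per (patient, chrom, pos, ref, alt);
2. records annotated to more than one gene symbol;
3. records whose reference context contains a tandem repeat at or above the
   thresholds: 6+ consecutive identical bases, 4+ tandem copies of a 2-mer,
   or 3+ tandem copies of a 3-, 4- or 5-mer;

followed by removal of explicitly excluded patients (e.g. hypermutated outliers).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "MutationRecord",
    "MafDialect",
    "FilterReport",
    "DEFAULT_DIALECT",
    "DEFAULT_REPEAT_THRESHOLDS",
    "read_maf",
    "write_maf",
    "dedup_same_patient",
    "drop_multi_gene",
    "repeat_context_pass",
    "max_tandem_copies",
    "run_filters",
]

#: strictly-below thresholds for tandem copy counts at unit lengths 1..5
DEFAULT_REPEAT_THRESHOLDS: tuple[int, ...] = (6, 4, 3, 3, 3)

_VALID_CONTEXT = frozenset("ACGTNacgtn")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant row of a MAF-like table.

    ``genes`` is a frozenset because TCGA legacy MAFs occasionally annotate a
    call to several overlapping/paralogous symbols; such records are the target
    of the gene-ambiguity filter. ``ref_context`` is the reference sequence
    centred on the variant position (11- or 21-mer depending on dialect).
    """

    patient_id: str
    sample_id: str
    genes: frozenset[str]
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_context: str
    variant_classification: str
    variant_type: str  # SNP / INS / DEL / other

    @property
    def gene(self) -> str:
        """The single gene symbol; only valid after drop_multi_gene."""
        if len(self.genes) != 1:
            raise ValueError(f"record maps to {len(self.genes)} genes: {sorted(self.genes)}")
        return next(iter(self.genes))

    @property
    def identity_key(self) -> tuple[str, str, int, str, str]:
        return (self.patient_id, self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class MafDialect:
    """Column-name mapping for a MAF-like TSV plus the barcode→patient rule."""

    sample_col: str = "Tumor_Sample_Barcode"
    gene_col: str = "Hugo_Symbol"
    chrom_col: str = "Chromosome"
    pos_col: str = "Start_position"
    ref_col: str = "Reference_Allele"
    alt_col: str = "Tumor_Seq_Allele2"
    context_col: str = "ref_context"
    classification_col: str = "Variant_Classification"
    type_col: str = "Variant_Type"
    patient_prefix_len: int = 12  # TCGA-XX-YYYY from TCGA-XX-YYYY-01A-...
    gene_separator: str = ";"

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (
            self.sample_col,
            self.gene_col,
            self.chrom_col,
            self.pos_col,
            self.ref_col,
            self.alt_col,
            self.context_col,
            self.classification_col,
        )

    def patient_of(self, barcode: str) -> str:
        return barcode[: self.patient_prefix_len]


DEFAULT_DIALECT = MafDialect()


@dataclass
class FilterReport:
    """Per-step accounting of the exclusion-filter chain."""

    n_input: int = 0
    n_after_dedup: int = 0
    n_after_gene_ambiguity: int = 0
    n_after_repeat_filter: int = 0
    n_after_patient_exclusion: int = 0

    @property
    def counts(self) -> tuple[int, ...]:
        return (
            self.n_input,
            self.n_after_dedup,
            self.n_after_gene_ambiguity,
            self.n_after_repeat_filter,
            self.n_after_patient_exclusion,
        )

    @property
    def fractions_removed(self) -> dict[str, float]:
        steps = ("dedup", "gene_ambiguity", "repeat_filter", "patient_exclusion")
        out: dict[str, float] = {}
        for name, before, after in zip(steps, self.counts[:-1], self.counts[1:]):
            out[name] = 0.0 if before == 0 else 1.0 - after / before
        return out

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_dedup": self.n_after_dedup,
            "n_after_gene_ambiguity": self.n_after_gene_ambiguity,
            "n_after_repeat_filter": self.n_after_repeat_filter,
            "n_after_patient_exclusion": self.n_after_patient_exclusion,
            "fractions_removed": self.fractions_removed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _parse_genes(raw: str, sep: str) -> frozenset[str]:
    parts = [g.strip() for g in str(raw).replace(",", sep).split(sep)]
    return frozenset(g for g in parts if g)


def read_maf(
    path,
    dialect: MafDialect = DEFAULT_DIALECT,
) -> tuple[list[MutationRecord], int]:
    """Read a MAF-like TSV into MutationRecords.

    Returns ``(records, n_dropped)`` where ``n_dropped`` counts rows whose
    mandatory fields could not be parsed (missing allele/context/position or a
    context containing characters outside A/C/G/T/N). Missing mandatory columns
    raise; an empty file returns an empty list with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    if df.empty and df.columns.size == 0:
        warnings.warn(f"empty MAF file: {path}", stacklevel=2)
        return [], 0
    missing = [c for c in dialect.mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"MAF {path} is missing mandatory column(s): {missing}")
    has_type = dialect.type_col in df.columns

    records: list[MutationRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        try:
            pos = int(float(d[dialect.pos_col]))
            context = str(d[dialect.context_col]).strip()
            genes = _parse_genes(d[dialect.gene_col], dialect.gene_separator)
            sample = str(d[dialect.sample_col]).strip()
            ref = str(d[dialect.ref_col]).strip()
            alt = str(d[dialect.alt_col]).strip()
            classification = str(d[dialect.classification_col]).strip()
            if not (context and genes and sample and ref and alt and classification):
                raise ValueError("empty mandatory field")
            if not set(context) <= _VALID_CONTEXT:
                raise ValueError("non-nucleotide context")
        except (ValueError, TypeError):
            n_dropped += 1
            continue
        vtype = str(d[dialect.type_col]).strip() if has_type else _infer_type(ref, alt)
        records.append(
            MutationRecord(
                patient_id=dialect.patient_of(sample),
                sample_id=sample,
                genes=genes,
                chrom=str(d[dialect.chrom_col]).strip(),
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                ref_context=context.upper(),
                variant_classification=classification,
                variant_type=vtype,
            )
        )
    if not records and n_dropped == 0:
        warnings.warn(f"empty MAF file: {path}", stacklevel=2)
    return records, n_dropped


def _infer_type(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1 and ref != "-" and alt != "-":
        return "SNP"
    if ref == "-" or len(alt) > len(ref):
        return "INS"
    if alt == "-" or len(ref) > len(alt):
        return "DEL"
    return "other"


def write_maf(records: list[MutationRecord], path, dialect: MafDialect = DEFAULT_DIALECT) -> None:
    rows = [
        {
            dialect.sample_col: r.sample_id,
            dialect.gene_col: dialect.gene_separator.join(sorted(r.genes)),
            dialect.chrom_col: r.chrom,
            dialect.pos_col: r.pos,
            dialect.ref_col: r.ref_allele,
            dialect.alt_col: r.alt_allele,
            dialect.context_col: r.ref_context,
            dialect.classification_col: r.variant_classification,
            dialect.type_col: r.variant_type,
        }
        for r in records
    ]
    cols = [
        dialect.sample_col, dialect.gene_col, dialect.chrom_col, dialect.pos_col,
        dialect.ref_col, dialect.alt_col, dialect.context_col,
        dialect.classification_col, dialect.type_col,
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def dedup_same_patient(records: list[MutationRecord]) -> tuple[list[MutationRecord], int]:
    """Keep one record per (patient, chrom, pos, ref, alt).

    Records are first stably sorted by sample_id so the survivor of a duplicate
    group is deterministic regardless of input row order.
    """
    ordered = sorted(records, key=lambda r: r.sample_id)
    seen: set[tuple] = set()
    kept: list[MutationRecord] = []
    for r in ordered:
        key = r.identity_key
        if key not in seen:
            seen.add(key)
            kept.append(r)
    return kept, len(records) - len(kept)


def drop_multi_gene(records: list[MutationRecord]) -> tuple[list[MutationRecord], int]:
    """Remove records annotated to more than one gene symbol."""
    kept = [r for r in records if len(r.genes) == 1]
    return kept, len(records) - len(kept)


def max_tandem_copies(context: str, unit: int) -> int:
    """Maximal number of consecutive tandem copies of any ``unit``-mer.

    A run of k identical bases counts as floor(k/unit) copies at unit length
    ``unit``. 'N' never matches anything, so it breaks every run.
    """
    s = context.upper()
    n = len(s)
    if n < unit:
        return 0
    best = 0
    for start in range(n - unit + 1):
        word = s[start : start + unit]
        if "N" in word:
            continue
        copies = 1
        pos = start + unit
        while pos + unit <= n and s[pos : pos + unit] == word:
            copies += 1
            pos += unit
        if copies > best:
            best = copies
    return best


def repeat_context_pass(
    context: str,
    thresholds: tuple[int, ...] = DEFAULT_REPEAT_THRESHOLDS,
) -> bool:
    """True iff the context stays strictly below every tandem-repeat threshold.

    thresholds[u-1] is the disallowed copy count at unit length u: with the
    defaults a context fails on >=6 consecutive identical bases, >=4 tandem
    2-mers, or >=3 tandem 3-/4-/5-mers. Case-insensitive; N breaks runs.
    """
    if not context:
        raise ValueError("empty ref_context")
    if not set(context) <= _VALID_CONTEXT:
        bad = sorted(set(context) - _VALID_CONTEXT)
        raise ValueError(f"ref_context contains non-nucleotide characters: {bad}")
    for unit, limit in enumerate(thresholds, start=1):
        if max_tandem_copies(context, unit) >= limit:
            return False
    return True


def run_filters(
    records: list[MutationRecord],
    excluded_patients: tuple[str, ...] = (),
    thresholds: tuple[int, ...] = DEFAULT_REPEAT_THRESHOLDS,
) -> tuple[list[MutationRecord], FilterReport]:
    """Apply the full exclusion chain and account for every step."""
    report = FilterReport(n_input=len(records))
    records, _ = dedup_same_patient(records)
    report.n_after_dedup = len(records)
    records, _ = drop_multi_gene(records)
    report.n_after_gene_ambiguity = len(records)
    records = [r for r in records if repeat_context_pass(r.ref_context, thresholds)]
    report.n_after_repeat_filter = len(records)
    excluded = set(excluded_patients)
    records = [r for r in records if r.patient_id not in excluded]
    report.n_after_patient_exclusion = len(records)
    return records, report
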