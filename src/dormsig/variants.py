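"""DNA vs RNA variant-allele-fraction concordance.

Pairs each sample's DNA-level driver call (gene, protein change, VAF %)
with the call observed in RNA-seq of the same sample and classifies the
pair:

* ``confirmed_same_site`` - identical gene and protein change at both
  levels; when both VAFs are present the pair is additionally labelled
  ``rna_higher`` / ``rna_lower`` / ``rna_equal`` by strict comparison.
* ``different_site`` - same gene but a different protein change in RNA.
* ``not_detected_rna`` - the RNA call is wild type.
* ``not_evaluable`` - the RNA (or DNA) call is missing or wild type at
  the DNA level, so transcription of the mutant allele cannot be judged.

Missing values are written ``NA`` (VAF columns) or ``-``/``NA`` (change
columns); ``WT`` marks an explicit wild-type call.  Gene symbols are
treated as opaque strings and never validated against a registry (the
cohort table preserves one obvious typo, ``BRAV``); pass an ``alias``
map, e.g. ``{"BRAV": "BRAF"}``, to fold such symbols at load time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "WILD_TYPE",
    "Category",
    "VafRelation",
    "ConcordanceCall",
    "normalize_variant_label",
    "classify_pair",
    "classify_table",
    "summarize_concordance",
]

WILD_TYPE = "WT"
_MISSING_TOKENS = {"", "-", "na", "n/a", "nan", "none"}
_CHANGE_RE = re.compile(r"^(?:P\.)?([A-Z*])(\d+)([A-Z*]+|=|DEL|INS|FS)$")
_LABEL_RE = re.compile(r"^([A-Z][A-Z0-9-]*)\s+(?:p\.)?(\S+)$", re.IGNORECASE)


class Category(str, Enum):
    CONFIRMED_SAME_SITE = "confirmed_same_site"
    DIFFERENT_SITE = "different_site"
    NOT_DETECTED_RNA = "not_detected_rna"
    NOT_EVALUABLE = "not_evaluable"


class VafRelation(str, Enum):
    RNA_HIGHER = "rna_higher"
    RNA_LOWER = "rna_lower"
    RNA_EQUAL = "rna_equal"
    NOT_COMPARABLE = "not_comparable"


@dataclass(frozen=True)
class ConcordanceCall:
    sample_id: str
    gene: str | None
    category: Category
    vaf_relation: VafRelation


def normalize_variant_label(raw) -> tuple[str | None, str] | str | None:
    """Normalize a printed variant label.

    Returns ``(gene, change)`` for labels like ``"BRAF p.V600E"`` (gene is
    ``None`` when only the change is given, e.g. ``"V600E"``), the string
    ``"WT"`` for wild-type markers, ``None`` for missing markers
    (``na``/``-``/empty), and raises for anything else.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if text.lower() in _MISSING_TOKENS:
        return None
    if text.upper() == WILD_TYPE:
        return WILD_TYPE
    m = _LABEL_RE.match(text)
    if m:
        gene, change = m.group(1).upper(), m.group(2).upper()
    else:
        gene, change = None, text.upper()
    if not _CHANGE_RE.match(change.removeprefix("P.") if change.startswith("P.") else change):
        raise ValueError(f"unrecognized variant label: {raw!r}")
    change = change.removeprefix("P.")
    return gene, change


def _normalize_vaf(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if text.lower() in _MISSING_TOKENS:
        return None
    vaf = float(text)
    if not 0.0 <= vaf <= 100.0:
        raise ValueError(f"VAF must be a percentage in [0, 100], got {value!r}")
    return vaf


def _change_of(label) -> str | None:
    """Collapse a normalized label to WT / None / plain change string."""
    norm = normalize_variant_label(label)
    if norm is None or norm == WILD_TYPE:
        return norm
    return norm[1]


def classify_pair(row: pd.Series | dict) -> ConcordanceCall:
    """Classify one sample's DNA/RNA variant pair (see module docstring)."""
    row = dict(row)
    sample = str(row.get("sample_id", ""))
    gene_raw = row.get("gene")
    gene = None if gene_raw is None or str(gene_raw).strip().lower() in _MISSING_TOKENS \
        else str(gene_raw).strip().upper()
    dna = _change_of(row.get("dna_variant"))
    rna = _change_of(row.get("rna_variant"))
    dna_vaf = _normalize_vaf(row.get("dna_vaf"))
    rna_vaf = _normalize_vaf(row.get("rna_vaf"))

    if dna is None or dna == WILD_TYPE or rna is None:
        category = Category.NOT_EVALUABLE
    elif rna == WILD_TYPE:
        category = Category.NOT_DETECTED_RNA
    elif rna == dna:
        category = Category.CONFIRMED_SAME_SITE
    else:
        category = Category.DIFFERENT_SITE

    relation = VafRelation.NOT_COMPARABLE
    if category is Category.CONFIRMED_SAME_SITE and dna_vaf is not None and rna_vaf is not None:
        if rna_vaf > dna_vaf:
            relation = VafRelation.RNA_HIGHER
        elif rna_vaf < dna_vaf:
            relation = VafRelation.RNA_LOWER
        else:
            relation = VafRelation.RNA_EQUAL
    return ConcordanceCall(sample_id=sample, gene=gene, category=category, vaf_relation=relation)


def classify_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """classify_pair over every row; returns sample_id, gene, category, vaf_relation."""
    calls = [classify_pair(row) for _, row in pairs.iterrows()]
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "gene": [c.gene if c.gene is not None else "NA" for c in calls],
            "category": [c.category.value for c in calls],
            "vaf_relation": [c.vaf_relation.value for c in calls],
        }
    )


def summarize_concordance(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene concordance counts.

    Columns partition the records: ``n_total = n_confirmed +
    n_different_site + n_not_detected + n_not_evaluable`` and
    ``n_rna_higher + n_rna_lower + n_rna_equal = n_with_both_vafs``.
    """
    columns = [
        "n_total",
        "n_confirmed",
        "n_with_both_vafs",
        "n_rna_higher",
        "n_rna_lower",
        "n_rna_equal",
        "n_different_site",
        "n_not_detected",
        "n_not_evaluable",
    ]
    if len(pairs) == 0:
        out = pd.DataFrame(columns=columns, dtype=int)
        out.index.name = "gene"
        return out
    calls = classify_table(pairs)
    rows = {}
    for gene, sub in calls.groupby("gene", sort=True):
        cat = sub["category"].value_counts()
        rel = sub["vaf_relation"].value_counts()
        higher = int(rel.get(VafRelation.RNA_HIGHER.value, 0))
        lower = int(rel.get(VafRelation.RNA_LOWER.value, 0))
        equal = int(rel.get(VafRelation.RNA_EQUAL.value, 0))
        rows[gene] = {
            "n_total": int(len(sub)),
            "n_confirmed": int(cat.get(Category.CONFIRMED_SAME_SITE.value, 0)),
            "n_with_both_vafs": higher + lower + equal,
            "n_rna_higher": higher,
            "n_rna_lower": lower,
            "n_rna_equal": equal,
            "n_different_site": int(cat.get(Category.DIFFERENT_SITE.value, 0)),
            "n_not_detected": int(cat.get(Category.NOT_DETECTED_RNA.value, 0)),
            "n_not_evaluable": int(cat.get(Category.NOT_EVALUABLE.value, 0)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")[columns].astype(int)
    out.index.name = "gene"
    return out
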