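"""Cross-condition comparison of strong-effect genes.

Given the condition-level fitness table, this module builds the
strong-effect gene set per condition, counts exclusive condition-subset
memberships (UpSet semantics), classifies each gene's pleiotropy pattern,
and tallies functional-category shares from an externally supplied
annotation table (e.g. KEGG BRITE output consumed as gene/category pairs).

Condition composition — which conditions contain phage and/or fungi — is
declared explicitly (a mapping from condition label to a set of agents),
never inferred from label strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import pandas as pd

PLEIOTROPY_CLASSES = (
    "antagonistic",
    "concordant-positive",
    "concordant-negative",
    "single-condition",
    "none",
)


def strong_calls(table: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Per condition: ``{gene: sign}`` over strong-effect genes."""
    strong = table[table["strong"]]
    out: dict[str, dict[str, int]] = {c: {} for c in table["condition"].unique()}
    for row in strong.itertuples(index=False):
        out[row.condition][row.locus_tag] = int(row.sign)
    return out


def membership_counts(sets: Mapping[str, set]) -> pd.DataFrame:
    """Exclusive gene counts for every nonempty condition subset.

    A gene counts toward exactly the subset of conditions in which it is
    strong, so counts over all subsets sum to the union size.
    """
    conditions = list(sets)
    if not conditions:
        raise ValueError("at least one condition required")
    membership: dict[str, frozenset] = {}
    for cond, genes in sets.items():
        for gene in genes:
            membership[gene] = membership.get(gene, frozenset()) | {cond}
    rows = []
    for r in range(1, len(conditions) + 1):
        for combo in combinations(conditions, r):
            key = frozenset(combo)
            n = sum(1 for m in membership.values() if m == key)
            rows.append({"conditions": "+".join(sorted(combo)), "n_conditions": r, "count": n})
    return pd.DataFrame(rows)


@dataclass
class PleiotropyCall:
    """Classification of one gene's cross-condition fitness pattern."""

    locus_tag: str
    pleiotropy_class: str
    phage_fungi_axis: bool
    n_strong: int
    calls: dict[str, int]


def classify_pleiotropy(
    table: pd.DataFrame,
    composition: Mapping[str, frozenset | set],
) -> pd.DataFrame:
    """Classify every gene that is strong in at least one condition.

    ``antagonistic`` = strong effects of opposite sign in >= 2 conditions.
    ``phage_fungi_axis`` additionally marks the trade-off pattern of
    interest here: strong-positive in a phage-containing condition and
    strong-negative in a fungi-without-phage condition (or vice versa) —
    the pattern O-antigen gene disruptions show under phage predation vs.
    fungal antagonism. Classification is order-invariant in the conditions.
    """
    calls_by_cond = strong_calls(table)
    genes = sorted({g for calls in calls_by_cond.values() for g in calls})
    rows = []
    for gene in genes:
        calls = {
            c: s for c, s in ((c, d.get(gene)) for c, d in calls_by_cond.items())
            if s is not None
        }
        signs = set(calls.values())
        pos = [c for c, s in calls.items() if s > 0]
        neg = [c for c, s in calls.items() if s < 0]

        def _phage(c):
            return "phage" in composition[c]

        def _fungi_only(c):
            return "fungi" in composition[c] and "phage" not in composition[c]

        axis = (any(_phage(c) for c in pos) and any(_fungi_only(c) for c in neg)) or (
            any(_phage(c) for c in neg) and any(_fungi_only(c) for c in pos)
        )
        if len(calls) >= 2 and len(signs) > 1:
            cls = "antagonistic"
        elif len(calls) == 1:
            cls = "single-condition"
        elif signs == {1}:
            cls = "concordant-positive"
        elif signs == {-1}:
            cls = "concordant-negative"
        else:
            cls = "none"
        rows.append(
            {
                "locus_tag": gene,
                "pleiotropy_class": cls,
                "phage_fungi_axis": bool(axis),
                "n_strong": len(calls),
                "calls": ";".join(f"{c}:{s:+d}" for c, s in sorted(calls.items())),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["locus_tag", "pleiotropy_class", "phage_fungi_axis", "n_strong", "calls"],
    )


def category_tally(
    strong_sets: Mapping[str, set],
    annotations: pd.DataFrame,
) -> tuple[pd.DataFrame, set[str]]:
    """Per-condition category shares among strong-effect genes.

    ``annotations`` holds one (locus_tag, category) pair per row. Two
    tallies are emitted for each category: its share of total *annotations*
    (a multi-annotated gene contributes once per category) and its share of
    annotated *genes* — both countings are reported side by side. Genes
    missing from the table are counted as unannotated. Returns the tally
    table and the set of categories present in every condition.
    """
    ann = annotations[["locus_tag", "category"]].drop_duplicates()
    by_gene = ann.groupby("locus_tag")["category"].apply(list)
    rows = []
    per_cond_cats: dict[str, set] = {}
    for cond, genes in strong_sets.items():
        cats: list[str] = []
        annotated_genes = 0
        unannotated = 0
        gene_hits: dict[str, int] = {}
        for gene in genes:
            labels = by_gene.get(gene)
            if not labels:
                unannotated += 1
                continue
            annotated_genes += 1
            cats.extend(labels)
            for lab in set(labels):
                gene_hits[lab] = gene_hits.get(lab, 0) + 1
        total = len(cats)
        per_cond_cats[cond] = set(cats)
        counts = pd.Series(cats).value_counts() if cats else pd.Series(dtype=int)
        for cat, n in counts.items():
            rows.append(
                {
                    "condition": cond,
                    "category": cat,
                    "n_annotations": int(n),
                    "pct_of_annotations": 100.0 * n / total,
                    "n_genes": gene_hits[cat],
                    "pct_of_genes": 100.0 * gene_hits[cat] / annotated_genes,
                    "n_unannotated_genes": unannotated,
                }
            )
    tally = pd.DataFrame(
        rows,
        columns=[
            "condition", "category", "n_annotations", "pct_of_annotations",
            "n_genes", "pct_of_genes", "n_unannotated_genes",
        ],
    )
    shared = (
        set.intersection(*per_cond_cats.values()) if per_cond_cats else set()
    )
    return tally, shared
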