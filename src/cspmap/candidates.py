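"""Broad-sense candidate selection and the merged candidate report.

A gene is a broad-sense candidate when it maps inside one of the co-required
loci AND carries a male-reproductive annotation term (tissue of expression
or function) from a configurable whitelist.  Term matching is exact-string
against a flat annotation table; no ontology traversal is attempted.  The
final report intersects the candidates with the expression screen's flags
and the per-lineage selection-test outcomes and tallies flagged genes per
cytogenetic band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd

from .bands import CytoBand, CytoInterval, parse_band
from .synthetic import MALE_REPRODUCTIVE_TERMS

__all__ = [
    "DEFAULT_TERM_WHITELIST",
    "GeneRecord",
    "in_locus",
    "broad_candidates",
    "final_report",
]

# Illustrative default whitelist of male reproduction terms; users supply
# their own list matching whatever annotation vocabulary their table uses.
DEFAULT_TERM_WHITELIST = frozenset(MALE_REPRODUCTIVE_TERMS) | frozenset(
    {"male", "sperm", "reproduction", "mating"})


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    band: CytoBand
    tissue_terms: frozenset
    function_terms: frozenset

    @classmethod
    def from_row(cls, row) -> "GeneRecord":
        split = lambda s: frozenset(t.strip() for t in str(s).split(";") if t.strip())
        return cls(gene_id=str(row["gene_id"]), band=parse_band(row["band"]),
                   tissue_terms=split(row.get("tissue_terms", "")),
                   function_terms=split(row.get("function_terms", "")))


def in_locus(gene: GeneRecord, loci: Sequence[CytoInterval]) -> bool:
    """True iff the gene's band falls inside any locus (inclusive ends)."""
    return any(loc.contains_band(gene.band) for loc in loci)


def broad_candidates(genes: Iterable[GeneRecord], loci: Sequence[CytoInterval],
                     term_whitelist: Iterable[str] = DEFAULT_TERM_WHITELIST
                     ) -> List[GeneRecord]:
    """Locus membership AND at least one whitelisted annotation term."""
    whitelist = set(term_whitelist)
    if not whitelist:
        raise ValueError("term whitelist must be non-empty")
    return [g for g in genes
            if in_locus(g, loci)
            and (g.tissue_terms & whitelist or g.function_terms & whitelist)]


def final_report(candidates: Sequence[GeneRecord],
                 expression_flags: Optional[pd.DataFrame] = None,
                 selection_results: Optional[pd.DataFrame] = None,
                 loci: Optional[Sequence[CytoInterval]] = None) -> Dict:
    """Merge the screens into a per-gene summary plus per-band counts.

    ``expression_flags`` is the screened fold table (gene + flag_* columns);
    ``selection_results`` has one row per gene x foreground lineage with a
    ``significant`` boolean (branch-site positive selection) and optional
    ``classification`` (accelerated/decelerated/unchanged).  Genes in the
    screens but absent from the candidate list are reported as mismatches,
    not errors.
    """
    cand_ids = {g.gene_id for g in candidates}
    expr: Dict[str, Dict] = {}
    if expression_flags is not None and len(expression_flags):
        flag_cols = [c for c in expression_flags.columns if c.startswith("flag_")]
        for _, row in expression_flags.iterrows():
            expr[str(row["gene"])] = {c: bool(row[c]) for c in flag_cols}
    sel: Dict[str, List[Dict]] = {}
    if selection_results is not None and len(selection_results):
        for _, row in selection_results.iterrows():
            sel.setdefault(str(row["gene"]), []).append({
                "foreground": str(row.get("foreground", "")),
                "significant": bool(row.get("significant", False)),
                "classification": str(row.get("classification", ""))})

    genes_out = []
    for g in sorted(candidates, key=lambda g: g.gene_id):
        flags = expr.get(g.gene_id, {})
        lineages = [s["foreground"] for s in sel.get(g.gene_id, []) if s["significant"]]
        genes_out.append({
            "gene_id": g.gene_id,
            "band": str(g.band),
            "locus": next((str(loc) for loc in (loci or [])
                           if loc.contains_band(g.band)), ""),
            "expression_flags": flags,
            "expression_candidate": any(flags.values()),
            "selection_lineages": sorted(lineages),
            "selection_candidate": bool(lineages),
        })
    flagged = [g for g in genes_out
               if g["expression_candidate"] or g["selection_candidate"]]
    band_counts: Dict[str, int] = {}
    for g in flagged:
        band_counts[g["band"]] = band_counts.get(g["band"], 0) + 1
    mismatches = sorted((set(expr) | set(sel)) - cand_ids)
    return {
        "n_candidates": len(genes_out),
        "n_flagged": len(flagged),
        "genes": genes_out,
        "per_band_flagged": dict(sorted(band_counts.items())),
        "unmatched_screen_genes": mismatches,
    }
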