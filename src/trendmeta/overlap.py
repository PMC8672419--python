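"""Cross-cohort overlap and gene-set over-representation analysis.

The headline statistic: given a blood gene list (m hits), a tissue gene
list (n hits) and a shared testable universe of N genes, the chance of
seeing at least k genes in both lists by draw alone is the hypergeometric
upper tail

    p = sum_{j=k}^{min(m,n)} C(m,j) C(N-m, n-j) / C(N,n).

The same tail probability, applied per gene set with Benjamini-Hochberg
control across sets, gives the over-representation analysis used for
dot-plot style pathway summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection
from .io import write_results_table

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "EnrichmentRecord",
    "hypergeometric_p",
    "intersect_and_score",
    "ora",
    "build_overlap_report",
]


def hypergeometric_p(k: int, m: int, n: int, universe: int) -> float:
    """Upper-tail P(X >= k) for drawing n of ``universe`` with m marked.

    Evaluated through the log-space survival function of the
    hypergeometric distribution for stability at extreme tails.
    """
    if m > universe or n > universe:
        raise ValueError(f"list sizes (m={m}, n={n}) exceed universe {universe}")
    if not 0 <= k <= min(m, n):
        raise ValueError(f"k={k} outside [0, min(m={m}, n={n})]")
    if k == 0:
        return 1.0
    # P(X >= k) = sf(k-1); exponentiate the log-sf to keep tiny tails exact
    logp = stats.hypergeom.logsf(k - 1, universe, m, n)
    return float(np.exp(logp))


@dataclass
class OverlapResult:
    """Intersection of blood and tissue significant sets over a shared universe."""

    blood_genes: tuple[str, ...]
    tissue_genes: tuple[str, ...]
    universe_size: int
    intersection: tuple[str, ...]
    p_value: float
    records: pd.DataFrame  # ranked: gene, p_eGWAS (meta), p_JT (trend)

    @property
    def k(self) -> int:
        return len(self.intersection)


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    p: float
    q: float
    passes: bool
    overlap_genes: tuple[str, ...] = ()


def intersect_and_score(
    blood_list: list[str],
    tissue_list: list[str],
    universe: list[str],
    blood_p: pd.Series | None = None,
    tissue_p: pd.Series | None = None,
    tissue_z: pd.Series | None = None,
) -> OverlapResult:
    """Intersect two significant gene lists and score the overlap.

    The universe must contain both lists (genes testable in both
    cohorts).  The ranked records are sorted by the trend p ascending
    with the meta p as tiebreak — the ordering a combined blood/tissue
    report table uses.
    """
    uni = set(universe)
    blood = [g for g in dict.fromkeys(blood_list)]
    tissue = [g for g in dict.fromkeys(tissue_list)]
    stray = (set(blood) | set(tissue)) - uni
    if stray:
        raise ValueError(f"genes outside the declared universe: {sorted(stray)[:10]}")
    if blood and tissue and not (set(blood) & uni and set(tissue) & uni):
        raise ValueError("no shared gene-id namespace between lists and universe")
    inter = sorted(set(blood) & set(tissue))
    n_universe = len(uni)
    p = hypergeometric_p(len(inter), len(blood), len(tissue), n_universe)
    records = pd.DataFrame(
        {
            "gene": inter,
            "p_eGWAS": [tissue_p.get(g, np.nan) if tissue_p is not None else np.nan for g in inter],
            "p_JT": [blood_p.get(g, np.nan) if blood_p is not None else np.nan for g in inter],
            "z_meta": [tissue_z.get(g, np.nan) if tissue_z is not None else np.nan for g in inter],
        }
    )
    records = records.sort_values(
        ["p_JT", "p_eGWAS", "gene"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    logger.info(
        "overlap: |blood|=%d |tissue|=%d universe=%d k=%d p=%.4g",
        len(blood),
        len(tissue),
        n_universe,
        len(inter),
        p,
    )
    return OverlapResult(tuple(blood), tuple(tissue), n_universe, tuple(inter), p, records)


def ora(
    gene_list: list[str],
    gene_sets: GeneSetCollection,
    universe: list[str],
    fdr_limit: float = 0.05,
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    Sets are intersected with the universe before testing; sets with no
    universe members are skipped (logged).  BH-adjusted q-values are
    computed across all tested sets and records come back sorted by
    (q, p).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    hits = set(gene_list) & uni
    if len(hits) < len(set(gene_list)):
        raise ValueError("gene_list contains genes outside the universe")
    names, pvals, rows = [], [], []
    for gene_set in gene_sets:
        members = set(gene_set.members) & uni
        if not members:
            logger.info("ora: set %r has no universe members; skipped", gene_set.name)
            continue
        overlap = sorted(hits & members)
        p = hypergeometric_p(len(overlap), len(members), len(hits), len(uni)) if hits else 1.0
        names.append(gene_set.name)
        pvals.append(p)
        rows.append((gene_set.name, overlap, len(members)))
    if not names:
        return []
    q = multipletests(pvals, method="fdr_bh")[1]
    records = [
        EnrichmentRecord(
            set_name=name,
            overlap=len(overlap),
            set_size=set_size,
            list_size=len(hits),
            universe_size=len(uni),
            p=float(p),
            q=float(qv),
            passes=bool(qv <= fdr_limit),
            overlap_genes=tuple(overlap),
        )
        for (name, overlap, set_size), p, qv in zip(rows, pvals, q)
    ]
    records.sort(key=lambda r: (r.q, r.p, r.set_name))
    return records


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Dot-plot-ready table (set, overlap/sizes, p, q, pass flag)."""
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "list_size": r.list_size,
                "universe_size": r.universe_size,
                "p": r.p,
                "q": r.q,
                "passes": r.passes,
            }
            for r in records
        ]
    )


def build_overlap_report(
    overlap: OverlapResult,
    enrichments: list[EnrichmentRecord],
    out_dir: str | Path,
) -> dict:
    """Write the ranked overlap table, the enrichment table and a JSON summary.

    Returns the summary dict (also written to ``summary.json``): stage
    counts, the hypergeometric p, and file names.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_path = out_dir / "overlap_table.tsv"
    enrich_path = out_dir / "enrichment.tsv"
    if overlap.k:
        write_results_table(overlap.records, table_path)
    else:
        write_results_table(
            pd.DataFrame(columns=["gene", "p_eGWAS", "p_JT", "z_meta"]), table_path
        )
    enrichment_frame(enrichments).to_csv(enrich_path, sep="\t", index=False)
    summary = {
        "n_blood_significant": len(overlap.blood_genes),
        "n_tissue_significant": len(overlap.tissue_genes),
        "universe_size": overlap.universe_size,
        "n_overlap": overlap.k,
        "hypergeometric_p": overlap.p_value,
        "n_gene_sets_tested": len(enrichments),
        "n_gene_sets_passing": sum(r.passes for r in enrichments),
        "files": {"overlap_table": table_path.name, "enrichment": enrich_path.name},
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
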