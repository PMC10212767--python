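"""Poly(A)-site usage shift test between conditions.

Genes with alternative cleavage-and-polyadenylation sites produce 3'-UTR
isoforms whose relative abundance is read directly off 3' end-seq counts.
For a (proximal, distal) site pair, the per-condition distal-to-proximal
ratio is (distal + c) / (proximal + c), and the between-condition usage
shift is the log2 of the pseudocounted odds ratio — equivalently
log2(ratio_B) - log2(ratio_A) — with a Wald p-value from the shared 2x2
machinery (a logistic regression of site choice on condition).  Genes with
more than two sites are screened pairwise (each-vs-proximal or
adjacent-pairs) with BH correction across all pairs in the run.

Replicate libraries are summed within condition before testing; replicate
variability is not modelled (a documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from iris.stats import adjust_fdr, table_stats

MODES = ("each-vs-proximal", "adjacent-pairs")
DEFAULT_SITE_WINDOW = 25


@dataclass
class SiteCountTable:
    """3' end-seq read counts per poly(A) site and condition for one gene.

    ``site_ids`` are ordered proximal -> distal along the 3'-UTR (5'->3' in
    transcript orientation); ``counts`` is indexed by site with one column
    per condition.
    """

    gene_id: str
    site_ids: tuple[str, ...]
    positions: tuple[int, ...]
    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.site_ids) < 2:
            raise ValueError(f"{self.gene_id}: need >= 2 poly(A) sites")
        if self.counts.shape[1] < 2:
            raise ValueError(f"{self.gene_id}: need >= 2 conditions")
        if list(self.counts.index) != list(self.site_ids):
            raise ValueError(f"{self.gene_id}: counts index must match site_ids order")
        if len(self.positions) != len(self.site_ids):
            raise ValueError(f"{self.gene_id}: positions/site_ids length mismatch")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError(f"{self.gene_id}: negative counts")

    @property
    def conditions(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ApaUsageResult:
    """Usage shift for one (proximal, distal) pair of one gene."""

    gene_id: str
    proximal: str
    distal: str
    log2_usage_shift: float
    p: float
    q: float = float("nan")
    ratios: dict = field(default_factory=dict)  # condition -> distal:proximal ratio
    untestable: bool = False


def distal_proximal_ratio(
    table: SiteCountTable,
    condition: str,
    pair: tuple[str, str] | None = None,
    pseudocount: float = 0.5,
) -> float:
    """(distal + c) / (proximal + c) for one condition."""
    prox, dist = pair if pair is not None else (table.site_ids[0], table.site_ids[-1])
    col = table.counts[condition]
    return float((col[dist] + pseudocount) / (col[prox] + pseudocount))


def usage_shift_test(
    table: SiteCountTable,
    cond_a: str,
    cond_b: str,
    pair: tuple[str, str] | None = None,
    pseudocount: float = 0.5,
) -> ApaUsageResult:
    """Test a proximal/distal pair for a usage shift between two conditions.

    log2_usage_shift is the pseudocounted log2 odds ratio of distal-site
    choice in B over A (exactly log2 ratio_B - log2 ratio_A); p is the Wald
    two-sided p-value.  A condition with zero reads at both sites makes the
    result untestable (p = 1).
    """
    prox, dist = pair if pair is not None else (table.site_ids[0], table.site_ids[-1])
    pa, da = (float(table.counts.loc[s, cond_a]) for s in (prox, dist))
    pb, db = (float(table.counts.loc[s, cond_b]) for s in (prox, dist))
    untestable = (pa + da == 0) or (pb + db == 0)
    shift, _, _, _, p = table_stats(db, pb, da, pa, pseudocount)
    ratios = {
        cond_a: distal_proximal_ratio(table, cond_a, (prox, dist), pseudocount),
        cond_b: distal_proximal_ratio(table, cond_b, (prox, dist), pseudocount),
    }
    return ApaUsageResult(
        gene_id=table.gene_id,
        proximal=prox,
        distal=dist,
        log2_usage_shift=float(shift),
        p=1.0 if untestable else float(p),
        ratios=ratios,
        untestable=untestable,
    )


def multi_site_scan(
    tables: Iterable[SiteCountTable] | SiteCountTable,
    cond_a: str,
    cond_b: str,
    mode: str = "each-vs-proximal",
    pseudocount: float = 0.5,
) -> list[ApaUsageResult]:
    """Pairwise usage tests over one or many genes, BH across all pairs.

    ``each-vs-proximal`` tests every non-proximal site against the most
    proximal one; ``adjacent-pairs`` tests consecutive site pairs.  A
    two-site gene reduces to its single pair under both modes.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if isinstance(tables, SiteCountTable):
        tables = [tables]
    results: list[ApaUsageResult] = []
    for table in tables:
        sites = table.site_ids
        if mode == "each-vs-proximal":
            pairs = [(sites[0], s) for s in sites[1:]]
        else:
            pairs = list(zip(sites[:-1], sites[1:]))
        for pair in pairs:
            results.append(usage_shift_test(table, cond_a, cond_b, pair, pseudocount))
    if results:
        q = adjust_fdr([r.p for r in results])
        for r, qv in zip(results, q):
            r.q = float(qv)
    return results


def results_to_frame(results: Sequence[ApaUsageResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "gene_id": r.gene_id,
            "proximal": r.proximal,
            "distal": r.distal,
            "log2_usage_shift": r.log2_usage_shift,
            "p": r.p,
            "q": r.q,
            "untestable": r.untestable,
        }
        for cond, ratio in r.ratios.items():
            row[f"ratio_{cond}"] = ratio
        rows.append(row)
    return pd.DataFrame(rows)


def assign_reads_to_sites(
    read_ends: Sequence[int],
    site_positions: Sequence[int],
    window: int = DEFAULT_SITE_WINDOW,
) -> np.ndarray:
    """Count 3' end-seq reads per annotated site.

    A read supports a site when its 3' terminus lies within +-``window`` nt
    of the site position; reads in range of several sites go to the nearest
    (ties to the more proximal, i.e. earlier-listed, site).
    """
    ends = np.asarray(read_ends)
    sites = np.asarray(site_positions)
    counts = np.zeros(len(sites), dtype=np.int64)
    if not len(ends):
        return counts
    dist = np.abs(ends[:, None] - sites[None, :])
    nearest = np.argmin(dist, axis=1)  # argmin takes the first (proximal) on ties
    in_range = dist[np.arange(len(ends)), nearest] <= window
    for site_idx in nearest[in_range]:
        counts[site_idx] += 1
    return counts


def read_site_counts(path: str | Path) -> list[SiteCountTable]:
    """Load the long-format counts TSV: gene, site, position, condition, count.

    Replicate rows (same gene/site/condition) are summed.  Site order is by
    ascending position within each gene (proximal -> distal).
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "site", "position", "condition", "count"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: counts table missing columns {sorted(missing)}")
    tables = []
    for gene, group in frame.groupby("gene", sort=True):
        pivot = (
            group.pivot_table(
                index=["site", "position"], columns="condition", values="count",
                aggfunc="sum", fill_value=0,
            )
            .reset_index()
            .sort_values("position")
        )
        site_ids = tuple(str(s) for s in pivot["site"])
        positions = tuple(int(p) for p in pivot["position"])
        counts = pivot.drop(columns=["site", "position"])
        counts.index = list(site_ids)
        tables.append(
            SiteCountTable(
                gene_id=str(gene), site_ids=site_ids, positions=positions, counts=counts
            )
        )
    return tables
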