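"""Competing-endogenous-RNA (ceRNA) scoring for tsRNA-miRNA pairs.

A miRNA and a tsRNA that share significantly many mRNA targets are
candidate competitors for the same binding sites. With N mRNAs in the
universe, K targeted by the miRNA, n targeted by the tsRNA and k shared,
the overlap is scored by the hypergeometric upper tail

    P = sum_{i=k..min(K,n)} C(K,i) C(N-K,n-i) / C(N,n)

and pairs passing Benjamini-Hochberg FDR < 0.05 become "competes" edges of
the ceRNA network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("tsrkit.cerna")


@dataclass
class CeRNATest:
    mirna_id: str
    tsrna_name: str
    N: int
    K: int
    n: int
    k: int
    pvalue: float
    fdr: float = float("nan")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) when drawing n of N objects, K of which are marked."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_cerna_network(
    tsrna_targets: pd.DataFrame,
    mirna_targets: pd.DataFrame,
    universe_size: int | None = None,
    fdr_threshold: float = 0.05,
) -> tuple[nx.DiGraph, pd.DataFrame]:
    """Score all (miRNA, tsRNA) pairs with shared targets and build the network.

    The input tables need columns (regulator_id, mRNA_id); rows are
    deduplicated. N defaults to the number of distinct mRNAs in the union of
    both tables. Pairs with no shared target are skipped (they cannot reach
    significance and would dilute the FDR correction).
    """
    ts_col, mi_col = list(tsrna_targets.columns[:2]), list(mirna_targets.columns[:2])
    ts_sets: dict[str, set[str]] = {}
    for reg, mrna in tsrna_targets[ts_col].drop_duplicates().itertuples(index=False):
        ts_sets.setdefault(str(reg), set()).add(str(mrna))
    mi_sets: dict[str, set[str]] = {}
    for reg, mrna in mirna_targets[mi_col].drop_duplicates().itertuples(index=False):
        mi_sets.setdefault(str(reg), set()).add(str(mrna))

    all_mrnas = sorted(set().union(*ts_sets.values(), *mi_sets.values(), set()))
    N = universe_size if universe_size is not None else len(all_mrnas)
    if N < len(all_mrnas):
        raise ValueError(
            f"universe size {N} smaller than the {len(all_mrnas)} distinct mRNAs observed"
        )

    tests: list[CeRNATest] = []
    n_skipped = 0
    for mirna in sorted(mi_sets):
        K = len(mi_sets[mirna])
        for tsrna in sorted(ts_sets):
            n = len(ts_sets[tsrna])
            k = len(mi_sets[mirna] & ts_sets[tsrna])
            if k == 0:
                n_skipped += 1
                continue
            tests.append(CeRNATest(
                mirna_id=mirna, tsrna_name=tsrna, N=N, K=K, n=n, k=k,
                pvalue=hypergeom_upper_tail(N, K, n, k),
            ))
    logger.info("ceRNA: %d pairs tested, %d pairs skipped (no shared target)",
                len(tests), n_skipped)
    if tests:
        for t, fdr in zip(tests, bh_fdr([t.pvalue for t in tests])):
            t.fdr = float(fdr)
    table = pd.DataFrame(
        [(t.mirna_id, t.tsrna_name, t.N, t.K, t.n, t.k, t.pvalue, t.fdr) for t in tests],
        columns=["mirna", "tsrna", "N", "K", "n", "k", "pvalue", "fdr"],
    )

    g = nx.DiGraph()
    for tsrna in sorted(ts_sets):
        g.add_node(tsrna, node_type="tsRNA")
    for mirna in sorted(mi_sets):
        g.add_node(mirna, node_type="miRNA")
    for mrna in all_mrnas:
        g.add_node(mrna, node_type="mRNA")
    for tsrna in sorted(ts_sets):
        for mrna in sorted(ts_sets[tsrna]):
            g.add_edge(tsrna, mrna, relation="targets")
    for mirna in sorted(mi_sets):
        for mrna in sorted(mi_sets[mirna]):
            g.add_edge(mirna, mrna, relation="targets")
    for t in tests:
        if t.fdr < fdr_threshold:
            g.add_edge(t.mirna_id, t.tsrna_name, relation="competes",
                       fdr=t.fdr, shared_targets=t.k)
    return g, table
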