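"""Preranked gene-set enrichment (weighted running-sum statistic).

Given a list of genes ranked by a signed metric (here log2FC) and a gene
set, the running sum increments at set members by |metric|^p normalized by
the summed |metric|^p over members, and decrements at non-members by
1/(N - n_hits).  The enrichment score (ES) is the signed value of maximal
absolute deviation from zero.  Significance comes from a gene-label
permutation null: random sets of the same size drawn from the ranked list.
p-values use the +1 correction against same-signed null scores, NES divides
ES by the mean |null ES| of the same sign, and FDR is BH across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import bh_adjust

__all__ = ["EnrichmentResult", "enrichment_score", "gsea_permutation"]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    q: float
    size: int
    running_sum: np.ndarray | None = None


def _hit_mask(genes: Sequence[str], gene_set: Sequence[str]) -> np.ndarray:
    members = set(gene_set)
    return np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))


def _es_from_mask(metric: np.ndarray, hits: np.ndarray, weight: float) -> tuple[float, np.ndarray]:
    n = len(metric)
    n_hits = int(hits.sum())
    w = np.abs(metric[hits]) ** weight
    w_sum = w.sum()
    steps = np.zeros(n)
    if w_sum > 0:
        steps[hits] = w / w_sum
    else:
        # all member metrics zero: flat hit weights
        steps[hits] = 1.0 / n_hits
    n_miss = n - n_hits
    if n_miss > 0:
        steps[~hits] = -1.0 / n_miss
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def enrichment_score(
    genes: Sequence[str],
    metric: Sequence[float],
    gene_set: Sequence[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """ES and running sum for one gene set against a ranked list.

    ``genes`` must be unique and ordered by decreasing metric; an empty
    intersection raises (callers skip such sets with a warning).
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    metric = np.asarray(metric, dtype=float)
    if len(metric) != len(genes):
        raise ValueError("metric length must match gene list")
    hits = _hit_mask(genes, gene_set)
    if not hits.any():
        raise ValueError("gene set does not intersect the ranked list")
    return _es_from_mask(metric, hits, weight)


def gsea_permutation(
    genes: Sequence[str],
    metric: Sequence[float],
    sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    keep_running_sum: bool = False,
) -> list[EnrichmentResult]:
    """Permutation-based enrichment over a collection of gene sets.

    The null for a set of size k is the ES of k positions drawn uniformly
    without replacement from the ranked list (gene-label permutation).
    Sets with no gene in the list are skipped with a warning; a set whose
    in-list size exceeds the list length is impossible and raises.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    genes = list(genes)
    metric = np.asarray(metric, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(genes)

    tested: list[tuple[str, int, float, np.ndarray | None]] = []
    sizes: set[int] = set()
    for name, members in sets.items():
        if len(set(members)) > n:
            raise ValueError(f"gene set {name} is larger than the ranked list")
        hits = _hit_mask(genes, members)
        k = int(hits.sum())
        if k == 0:
            warnings.warn(f"gene set {name} does not intersect the ranked list; skipped")
            continue
        es, running = _es_from_mask(metric, hits, weight)
        tested.append((name, k, es, running if keep_running_sum else None))
        sizes.add(k)

    # one shared null per set size: permutation distribution depends on the
    # metric and k only
    null_by_size: dict[int, np.ndarray] = {}
    for k in sorted(sizes):
        null = np.empty(n_perm)
        mask = np.zeros(n, dtype=bool)
        for b in range(n_perm):
            mask[:] = False
            mask[rng.choice(n, size=k, replace=False)] = True
            null[b], _ = _es_from_mask(metric, mask, weight)
        null_by_size[k] = null

    results = []
    pvals = []
    for name, k, es, running in tested:
        null = null_by_size[k]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        n_extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (1.0 + n_extreme) / (1.0 + n_same)
        denom = np.abs(null[same_sign]).mean() if n_same else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        pvals.append(p)
        results.append(EnrichmentResult(name, es, float(nes), p, np.nan, k, running))

    q = bh_adjust(np.array(pvals)) if pvals else np.array([])
    for r, qi in zip(results, q):
        r.q = float(qi)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "ES": [r.es for r in results],
            "NES": [r.nes for r in results],
            "p": [r.p_perm for r in results],
            "q": [r.q for r in results],
            "size": [r.size for r in results],
        }
    )
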