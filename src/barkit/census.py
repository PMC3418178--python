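"""Barcode census: abundance tables, error collapse and selection statistics.

A census counts how often each barcode is seen in each sampled pool.
Sequencing errors scatter a true barcode into low-count neighbours within a
small edit distance; those are absorbed back into their high-count parent by
a directional collapse (the same idea used by UMI deduplication tools).
Downstream, per-barcode changes in proportion between a pre- and
post-selection sample flag enriched or depleted mutants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .oligomer import BarcodeCall, CallStatus

__all__ = [
    "CensusTable",
    "CollapseRecord",
    "tally_and_collapse",
    "proportion_estimate",
    "abundance_change",
    "ProportionEstimate",
]


@dataclass(frozen=True)
class CollapseRecord:
    child: str
    parent: str
    count: int


@dataclass
class CensusTable:
    """Per-sample barcode counts plus the provenance of error-collapse.

    ``counts`` is a DataFrame indexed by barcode with one integer column per
    sample.
    """

    counts: pd.DataFrame
    collapse_log: list[CollapseRecord] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.index)

    def total(self, sample: str) -> int:
        return int(self.counts[sample].sum())


def _call_seqs(calls: Iterable[BarcodeCall | str]) -> list[str]:
    out = []
    for c in calls:
        if isinstance(c, str):
            out.append(c)
        elif c.status == CallStatus.passed:
            out.append(c.seq)
        else:
            raise ValueError("census accepts only calls with status 'pass'")
    return out


def tally_and_collapse(
    calls_by_sample: Mapping[str, Iterable[BarcodeCall | str]],
    max_edit: int = 4,
    ratio: float = 2.0,
) -> CensusTable:
    """Exact tally followed by directional merge of error neighbours.

    Barcodes are processed in ascending total count (ties lexicographic,
    which makes the result order-independent); each barcode ``b`` is
    absorbed into the highest-count retained barcode ``a`` with
    ``edit(a, b) <= max_edit`` and ``count(a) >= ratio * count(b)``.
    Total counts are conserved.
    """
    per_sample: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for sample, calls in calls_by_sample.items():
        tab: dict[str, int] = {}
        for s in _call_seqs(calls):
            tab[s] = tab.get(s, 0) + 1
            totals[s] = totals.get(s, 0) + 1
        per_sample[sample] = tab

    # descending count, lexicographic ties: deterministic parent preference
    order = sorted(totals, key=lambda b: (-totals[b], b))
    retained: list[str] = []
    parent_of: dict[str, str] = {}
    log: list[CollapseRecord] = []
    for b in reversed(order):  # smallest first
        cnt = totals[b]
        chosen = None
        for a in order:  # largest first
            if a == b or parent_of.get(a) is not None:
                continue
            if totals[a] < ratio * cnt:
                break  # order is sorted descending; no later a can qualify
            res = edlib.align(b, a, k=max_edit)
            if res["editDistance"] != -1:
                chosen = a
                break
        if chosen is not None:
            parent_of[b] = chosen
            log.append(CollapseRecord(b, chosen, cnt))

    # resolve chains child -> parent -> grandparent
    def root(b: str) -> str:
        while b in parent_of:
            b = parent_of[b]
        return b

    samples = list(calls_by_sample)
    collapsed: dict[str, dict[str, int]] = {s: {} for s in samples}
    for s in samples:
        for b, c in per_sample[s].items():
            r = root(b)
            collapsed[s][r] = collapsed[s].get(r, 0) + c
    barcodes = sorted({b for s in samples for b in collapsed[s]})
    df = pd.DataFrame(
        {s: [collapsed[s].get(b, 0) for b in barcodes] for s in samples},
        index=pd.Index(barcodes, name="barcode"),
        dtype=int,
    )
    return CensusTable(df, log)


@dataclass(frozen=True)
class ProportionEstimate:
    point: float
    lower: float
    upper: float
    k: int
    n: int
    level: float


def proportion_estimate(k: int, n: int, level: float = 0.95) -> ProportionEstimate:
    """Point estimate k/n with a Wilson score interval (stable at small n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    lo = 0.0 if k == 0 else float(lo)  # exact boundary, not float residue
    hi = 1.0 if k == n else float(hi)
    return ProportionEstimate(k / n, lo, hi, k, n, level)


def abundance_change(
    table: CensusTable,
    pre_sample: str,
    post_sample: str,
    pseudocount: float = 0.5,
    depleted_at: float = -2.0,
    enriched_at: float = 2.0,
) -> pd.DataFrame:
    """Per-barcode log2 ratio of proportions between two samples.

    score = log2( ((c_post+pc)/N_post) / ((c_pre+pc)/N_pre) ); barcodes with
    zero counts in both samples are excluded.  Swapping the samples negates
    every score.
    """
    for s in (pre_sample, post_sample):
        if s not in table.counts.columns:
            raise KeyError(f"sample {s!r} not in census table")
    pre = table.counts[pre_sample]
    post = table.counts[post_sample]
    keep = (pre > 0) | (post > 0)
    pre, post = pre[keep], post[keep]
    n_pre, n_post = pre.sum(), post.sum()
    score = np.log2(((post + pseudocount) / n_post) / ((pre + pseudocount) / n_pre))
    out = pd.DataFrame(
        {
            "count_pre": pre,
            "count_post": post,
            "log2_ratio": score,
            "depleted": score <= depleted_at,
            "enriched": score >= enriched_at,
        }
    )
    return out.sort_values("log2_ratio")
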