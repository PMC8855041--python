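"""Locus-level quality control: gap-threshold column trimming, the
matched-pairs (Bowker) test of symmetry used to drop model-violating
loci, parsimony-informative-site counts, and per-dataset summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io_core import MISSING_CODE, MultipleAlignment

__all__ = [
    "SummaryTable",
    "trim_gapped_columns",
    "bowker_symmetry_test",
    "filter_loci_symtest",
    "count_pis",
    "summarize_dataset",
]


class UndefinedTestError(ValueError):
    """Two rows share no called sites; the symmetry test is undefined."""


def trim_gapped_columns(aln: MultipleAlignment,
                        gt: float = 0.2) -> MultipleAlignment:
    """Drop columns whose fraction of non-gap characters falls below ``gt``.

    This is the trimAl ``-gt`` rule: with ``gt=0.2`` a column is removed
    when more than 80% of its characters are gaps.  Columns at exactly
    the threshold are kept; column order is preserved.  ``N`` counts as
    missing, consistently with every other statistic here.
    """
    if not (0.0 < gt <= 1.0):
        raise ValueError("gt must be in (0, 1]")
    if aln.n_sites == 0:
        raise ValueError("empty alignment")
    codes = aln.codes()
    called_frac = (codes != MISSING_CODE).mean(axis=0)
    keep = called_frac >= gt
    if not keep.any():
        raise ValueError(f"{aln.locus_id}: no columns survive trimming")
    return MultipleAlignment(aln.locus_id, aln.class_tag, list(aln.taxa),
                             aln.matrix[:, keep])


def bowker_symmetry_test(seq_i: np.ndarray, seq_j: np.ndarray
                         ) -> tuple[float, int, float]:
    """Matched-pairs test of symmetry between two aligned sequences.

    Over sites where both sequences have called bases, with ``n_xy`` the
    count of sites showing state ``x`` in one sequence and ``y`` in the
    other, the statistic is ``X^2 = sum_{x<y} (n_xy - n_yx)^2 / (n_xy +
    n_yx)`` over pairs with a nonzero denominator; the degrees of
    freedom equal the number of such pairs.  A significant value flags a
    violation of evolution under a stationary, reversible, homogeneous
    model.  Returns ``(statistic, df, p)``; ``df = 0`` gives ``p = 1``.
    """
    ci = _as_codes(seq_i)
    cj = _as_codes(seq_j)
    both = (ci != MISSING_CODE) & (cj != MISSING_CODE)
    if not both.any():
        raise UndefinedTestError("no shared called sites")
    a, b = ci[both], cj[both]
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    stat = 0.0
    df = 0
    for x in range(4):
        for y in range(x + 1, 4):
            tot = counts[x, y] + counts[y, x]
            if tot > 0:
                stat += (counts[x, y] - counts[y, x]) ** 2 / tot
                df += 1
    p = 1.0 if df == 0 else float(chi2.sf(stat, df))
    return float(stat), df, p


def _as_codes(seq) -> np.ndarray:
    arr = np.asarray(seq)
    if arr.dtype == np.uint8:
        return arr
    from .io_core import _CODE
    return _CODE[np.char.upper(arr.astype("S1")).view(np.uint8)]


def filter_loci_symtest(loci: list[MultipleAlignment], alpha: float = 0.05,
                        min_overlap: int = 50
                        ) -> tuple[list[MultipleAlignment],
                                   list[MultipleAlignment], pd.DataFrame]:
    """Exclude loci that fail the pairwise symmetry test.

    For each locus, Bowker tests run over all taxon pairs with at least
    ``min_overlap`` shared called sites; the locus p-value is the one
    belonging to the pair with the largest statistic (no multiple-test
    correction), and the locus is removed when that p-value falls below
    ``alpha``.  Loci with no testable pair are kept and flagged in the
    report.
    """
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must be in [0, 1)")
    kept, removed, rows = [], [], []
    for aln in loci:
        codes = aln.codes()
        called = codes != MISSING_CODE
        best = None  # (stat, df, p)
        testable = False
        n = aln.n_taxa
        for i in range(n):
            for j in range(i + 1, n):
                overlap = int((called[i] & called[j]).sum())
                if overlap < min_overlap:
                    continue
                testable = True
                stat, df, p = bowker_symmetry_test(codes[i], codes[j])
                if best is None or stat > best[0]:
                    best = (stat, df, p)
        if not testable:
            kept.append(aln)
            rows.append((aln.locus_id, aln.class_tag, np.nan, np.nan,
                         True, False))
            continue
        stat, df, p = best
        drop = p < alpha
        (removed if drop else kept).append(aln)
        rows.append((aln.locus_id, aln.class_tag, stat, p, False, drop))
    report = pd.DataFrame(
        rows, columns=["locus_id", "class", "max_statistic", "p_value",
                       "untestable", "removed"])
    return kept, removed, report


def count_pis(aln: MultipleAlignment) -> int:
    """Number of parsimony-informative sites.

    A column is informative when at least two distinct called states
    each occur in at least two sequences; gaps and ``N`` are ignored.
    """
    codes = aln.codes()
    n_informative = 0
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])
    n_informative = int(((counts >= 2).sum(axis=0) >= 2).sum())
    return n_informative


def _column_pis_mask(codes: np.ndarray) -> np.ndarray:
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])
    return (counts >= 2).sum(axis=0) >= 2


@dataclass
class SummaryTable:
    """Per-dataset alignment summary (one row per locus class / dataset)."""

    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def summarize_dataset(loci: list[MultipleAlignment],
                      dataset: str = "dataset") -> SummaryTable:
    """Tabulate total length, PIS, base composition, locus-length range
    and missing-data percentage for one locus collection."""
    if not loci:
        raise ValueError("no loci to summarize")
    lengths = np.array([a.n_sites for a in loci])
    total = int(lengths.sum())
    pis = sum(count_pis(a) for a in loci)
    at = gc = called = missing = cells = 0
    for a in loci:
        codes = a.codes()
        at += int(((codes == 0) | (codes == 3)).sum())
        gc += int(((codes == 1) | (codes == 2)).sum())
        miss = int((codes == MISSING_CODE).sum())
        missing += miss
        cells += codes.size
        called += codes.size - miss
    row = {
        "dataset": dataset,
        "n_loci": len(loci),
        "total_length_bp": total,
        "pis": pis,
        "pis_pct": 100.0 * pis / total,
        "at_pct": 100.0 * at / called if called else np.nan,
        "gc_pct": 100.0 * gc / called if called else np.nan,
        "min_length": int(lengths.min()),
        "max_length": int(lengths.max()),
        "avg_length": float(lengths.mean()),
        "missing_pct": 100.0 * missing / cells,
    }
    return SummaryTable(pd.DataFrame([row]))
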