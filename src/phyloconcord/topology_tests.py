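"""RELL-based Shimodaira-Hasegawa (SH) and approximately unbiased (AU)
topology tests of a candidate tree set against a fixed reference.

Both tests work from a trees x sites matrix of per-site log-likelihoods
on one evaluation alignment.  RELL (resampling estimated log
likelihood) bootstraps site weights without re-optimizing trees; the AU
test fits the standard multiscale-bootstrap correction (normal-quantile
regression of bootstrap proportions on scale) so that selection bias of
picking the best tree is accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_core import MultipleAlignment, PhyloTree, TreeCollection, leaf_labels
from .phylo_engine import SiteLikelihoodMatrix, optimize_branch_lengths
from .simulate import JC69, SubstitutionModel

__all__ = [
    "TestConfig",
    "TopologyTestReport",
    "rell_resample",
    "sh_test",
    "au_test",
    "compare_to_fixed",
]

_TIE_TOL = 1e-9


@dataclass
class TestConfig:
    """RELL replicate count, AU scales, rejection level, and seed."""

    __test__ = False  # not a pytest class despite the name

    B: int = 10_000
    scales: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
                                 1.1, 1.2, 1.3, 1.4)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 100:
            raise ValueError("B must be at least 100")
        if not any(abs(s - 1.0) < 1e-12 for s in self.scales):
            raise ValueError("scales must include 1.0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")


@dataclass
class TopologyTestReport:
    """Per-candidate totals, deltas to the best tree, and p-values."""

    table: pd.DataFrame
    alpha: float
    flags: dict = field(default_factory=dict)

    def __str__(self) -> str:
        return self.table.to_string(index=False)

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def rell_resample(L: SiteLikelihoodMatrix, B: int, scale: float = 1.0,
                  seed: int = 0, chunk: int = 1000) -> np.ndarray:
    """(B, n_trees) matrix of RELL replicate log-likelihoods.

    Each replicate draws ``round(scale * n_sites)`` sites with
    replacement (the same draw for every tree) and sums the per-site
    log-likelihoods.  Implemented as multinomial site weights times the
    likelihood matrix, in chunks to bound memory.  Deterministic given
    ``seed``.
    """
    if L.matrix.size == 0:
        raise ValueError("empty site-likelihood matrix")
    if scale <= 0:
        raise ValueError("scale must be positive")
    n = L.n_sites
    m = max(1, int(round(scale * n)))
    rng = np.random.default_rng(seed)
    p = np.full(n, 1.0 / n)
    out = np.empty((B, L.matrix.shape[0]))
    Lt = L.matrix.T  # (n_sites, n_trees)
    done = 0
    while done < B:
        b = min(chunk, B - done)
        counts = rng.multinomial(m, p, size=b).astype(float)
        out[done:done + b] = counts @ Lt
        done += b
    return out


def sh_test(L: SiteLikelihoodMatrix, cfg: TestConfig | None = None
            ) -> np.ndarray:
    """Shimodaira-Hasegawa p-value per tree.

    Observed deltas to the best tree are compared with centered RELL
    replicate deltas; the best tree always receives p = 1.  A single
    tree returns p = 1 by convention.
    """
    cfg = cfg or TestConfig()
    totals = L.totals()
    T = len(totals)
    if T == 1:
        return np.array([1.0])
    delta = totals.max() - totals
    R = rell_resample(L, cfg.B, scale=1.0, seed=cfg.seed)
    Rc = R - R.mean(axis=0, keepdims=True)
    D = Rc.max(axis=1, keepdims=True) - Rc  # (B, T)
    return (D >= delta[None, :] - _TIE_TOL).mean(axis=0)


def _bootstrap_proportions(R: np.ndarray) -> np.ndarray:
    """Fraction of replicates where each tree attains the maximum,
    exact ties split equally among the tied trees."""
    mx = R.max(axis=1, keepdims=True)
    tied = R >= mx - _TIE_TOL
    w = tied / tied.sum(axis=1, keepdims=True)
    return w.mean(axis=0)


def au_test(L: SiteLikelihoodMatrix, cfg: TestConfig | None = None
            ) -> tuple[np.ndarray, dict]:
    """Approximately-unbiased p-value per tree via multiscale RELL.

    For every scale r, the bootstrap proportion BP (share of replicates
    in which the tree is best) is converted to a normal quantile
    z = Phi^-1(1 - BP) and regressed on d*sqrt(r) + c/sqrt(r) by
    weighted least squares; p_AU = 1 - Phi(d - c).  Degenerate BP
    profiles (0 or 1 at every scale) return 0/1 with a flag; a singular
    fit falls back to the SH p-value with a warning flag.
    """
    cfg = cfg or TestConfig()
    if len(cfg.scales) < 2:
        raise ValueError("AU test needs at least 2 scales")
    T = L.matrix.shape[0]
    B = cfg.B
    scales = np.asarray(cfg.scales)
    BP = np.empty((len(scales), T))
    for si, r in enumerate(scales):
        R = rell_resample(L, B, scale=float(r),
                          seed=cfg.seed + 7919 * si)
        BP[si] = _bootstrap_proportions(R)

    eps = 1.0 / (2.0 * B)
    flags: dict = {}
    p = np.empty(T)
    sh_fallback = None
    for t in range(T):
        bp = BP[:, t]
        if np.all(bp <= eps):
            p[t] = 0.0
            flags[t] = "degenerate_low"
            continue
        if np.all(bp >= 1.0 - eps):
            p[t] = 1.0
            flags[t] = "degenerate_high"
            continue
        bpc = np.clip(bp, eps, 1.0 - eps)
        z = norm.ppf(1.0 - bpc)
        w = B * norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
        X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
            d_hat, c_hat = beta
            p[t] = float(1.0 - norm.cdf(d_hat - c_hat))
        except np.linalg.LinAlgError:
            if sh_fallback is None:
                sh_fallback = sh_test(L, cfg)
            p[t] = sh_fallback[t]
            flags[t] = "fit_failed_sh_substituted"
    return p, flags


def compare_to_fixed(fixed: PhyloTree, candidates: TreeCollection,
                     eval_alignment: MultipleAlignment,
                     cfg: TestConfig | None = None,
                     model: SubstitutionModel = JC69,
                     ) -> TopologyTestReport:
    """SH and AU tests of every candidate tree against a fixed tree.

    Branch lengths of the fixed tree and every candidate are re-optimized
    on the evaluation alignment (RELL requires per-site log-likelihoods
    under one common alignment); the per-site matrix then feeds both
    tests.  The report has one row per candidate, in collection order,
    with +/- acceptance at ``cfg.alpha``.
    """
    cfg = cfg or TestConfig()
    leafset = leaf_labels(fixed)
    for (ds, meth), t in candidates:
        if leaf_labels(t) != leafset:
            raise ValueError(
                f"candidate ({ds}, {meth}) leaf set differs from the "
                "fixed tree; harmonize first")

    ids = ["fixed"] + [f"{ds}/{meth}" for (ds, meth), _ in candidates]
    trees = [fixed] + [t for _, t in candidates]
    rows = []
    for t in trees:
        _, per_site, _ = optimize_branch_lengths(t, eval_alignment, model,
                                                 max_sweeps=8)
        rows.append(per_site)
    L = SiteLikelihoodMatrix(ids, np.stack(rows))
    p_sh = sh_test(L, cfg)
    p_au, flags = au_test(L, cfg)
    totals = L.totals()
    best = totals.max()

    records = []
    for i, ((ds, meth), _t) in enumerate(candidates, start=1):
        records.append({
            "dataset": ds,
            "tree": meth,
            "lnL": totals[i],
            "delta_lnL": best - totals[i],
            "SH_p": p_sh[i],
            "SH": "+" if p_sh[i] >= cfg.alpha else "-",
            "AU_p": p_au[i],
            "AU": "+" if p_au[i] >= cfg.alpha else "-",
        })
    report = TopologyTestReport(pd.DataFrame(records), cfg.alpha,
                                flags={ids[k]: v for k, v in flags.items()})
    report.site_likelihoods = L
    return report
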