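"""Branch-site models on a designated foreground branch set.

Site classes follow the Model A construction: class 0 evolves with
omega0 < 1 everywhere, class 1 neutrally everywhere; classes 2a and 2b
take omega2 >= 1 on the foreground branches while keeping omega0 / 1 on
the background, with proportions tied as p2a/p2b = p0/p1.  The site model
M1a is the same mixture without the 2a/2b classes; the null Model A pins
omega2 = 1.  Tests 1 (Model A vs M1a, df 2) and 2 (Model A vs null
Model A, df 1) are the standard positive-selection LRT pair, and sites
are identified by Bayes empirical Bayes: the posterior probability of
membership in the foreground-selected classes, integrated over a prior
grid on (p0, p1, omega0, omega2) with the remaining parameters at their
MLEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
from scipy.special import logsumexp

from .branch_models import ModelContext, lrt
from .codon_model import OMEGA_CAP, substitution_rate
from .seq_tree_io import CodonAlignment, PhyloTree

_LOG_T_BOUNDS = (math.log(1e-7), math.log(20.0))
_LOG_K_BOUNDS = (math.log(1e-3), math.log(100.0))
_MIX_BOUND = 30.0  # bound on the mixing logits
_W0_EPS = 1e-6


@dataclass
class SiteClassFit:
    """A fitted site / branch-site mixture model."""

    model: str  # M1a | ModelA | ModelA_fixed
    lnL: float
    np: int
    p0: float
    p1: float
    p2a: float
    p2b: float
    omega0: float
    omega2: float
    kappa_hat: float
    branch_lengths_hat: np.ndarray
    converged: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def proportions(self) -> tuple[float, float, float, float]:
        return (self.p0, self.p1, self.p2a, self.p2b)


@dataclass
class BEBReport:
    """Per-site posterior of the positively selected classes."""

    posterior: np.ndarray  # per codon site, P(class 2a or 2b | data)
    flagged_sites: list[tuple[int, str, float]]  # (1-based site, residue, posterior)
    threshold: float = 0.95


def _mixture_scale(
    ctx: ModelContext, kappa: float, weights: np.ndarray, omega0: float
) -> float:
    """Shared generator scale for a site-class mixture.

    Branch lengths are expected substitutions per codon under the
    background regime, averaging class rates by their proportions (class
    0/2a at omega0, class 1/2b neutral), so that a site in a fast class
    really does accumulate more changes than a conserved one.
    """
    r0 = ctx.rate(kappa, omega0)
    r1 = ctx.rate(kappa, 1.0)
    if len(weights) == 2:
        return float(weights[0] * r0 + weights[1] * r1)
    return float((weights[0] + weights[2]) * r0 + (weights[1] + weights[3]) * r1)


def _stacked_class_logliks(
    ctx: ModelContext,
    foreground: set[int],
    kappa: float,
    lengths: np.ndarray,
    class_omegas: list[tuple[float, float]],  # (background, foreground) per class
    scale: float,
) -> np.ndarray:
    """Per-pattern log likelihoods of several site classes in one pass.

    Returns a (C, n_patterns) array; all classes share kappa, lengths and
    the mixture scale, differing only in their background / foreground
    omegas.
    """
    distinct = sorted({w for pair in class_omegas for w in pair})
    branch_ids = [b.branch_id for b in ctx.tree.branches]
    ts = np.array([float(lengths[b]) for b in branch_ids])
    # exp((Q/scale) t) = exp((Q/r) (t r/scale)): reuse self-scaled eigens
    # across evals, folding the mixture scale into the branch lengths
    p_by_omega = {
        w: ctx.eigen(kappa, w).transitions(ts * (ctx.rate(kappa, w) / scale))
        for w in distinct
    }  # each (B, 61, 61)
    fg_mask = np.array([b in foreground for b in branch_ids])
    per_class = []
    for w_bg, w_fg in class_omegas:
        if w_bg == w_fg or not fg_mask.any():
            per_class.append(p_by_omega[w_bg])
        else:
            pc = p_by_omega[w_bg].copy()
            pc[fg_mask] = p_by_omega[w_fg][fg_mask]
            per_class.append(pc)
    big = np.stack(per_class)  # (C, B, 61, 61)
    p_of_branch = {b: big[:, i] for i, b in enumerate(branch_ids)}
    return ctx.engine.site_pattern_logliks_multi(p_of_branch, ctx.freqs)


def _class_site_logliks(
    ctx: ModelContext,
    foreground: set[int],
    kappa: float,
    lengths: np.ndarray,
    omega_bg: float,
    omega_fg: float,
    scale: float,
) -> np.ndarray:
    """Per-pattern log likelihood with one omega on background branches
    and another on the foreground set, under a shared mixture scale."""
    e_bg = ctx.eigen(kappa, omega_bg)
    e_fg = ctx.eigen(kappa, omega_fg)
    f_bg = ctx.rate(kappa, omega_bg) / scale
    f_fg = ctx.rate(kappa, omega_fg) / scale
    bg_ids = [b.branch_id for b in ctx.tree.branches if b.branch_id not in foreground]
    fg_ids = [b.branch_id for b in ctx.tree.branches if b.branch_id in foreground]
    p: dict[int, np.ndarray] = {}
    if bg_ids:
        p.update(
            zip(bg_ids, e_bg.transitions([float(lengths[b]) * f_bg for b in bg_ids]))
        )
    if fg_ids:
        p.update(
            zip(fg_ids, e_fg.transitions([float(lengths[b]) * f_fg for b in fg_ids]))
        )
    return ctx.engine.site_pattern_logliks(p, ctx.freqs)


def _mixture_lnl(weights: np.ndarray, class_logliks: list[np.ndarray], counts) -> float:
    stack = np.stack(class_logliks)  # (n_classes, n_patterns)
    logw = np.log(np.maximum(weights, 1e-300))[:, None]
    per_pattern = logsumexp(stack + logw, axis=0)
    return float(counts @ per_pattern)


def _model_a_weights(a: float, b: float) -> tuple[float, float, float, float]:
    """Map two logits to (p0, p1, p2a, p2b) with p2a/p2b = p0/p1."""
    ea, eb = math.exp(a), math.exp(b)
    z = ea + eb + 1.0
    p0, p1 = ea / z, eb / z
    rest = 1.0 / z
    denom = p0 + p1
    return p0, p1, rest * p0 / denom, rest * p1 / denom


def fit_site_model(
    aln: CodonAlignment | None,
    tree: PhyloTree | None,
    foreground: set[int],
    model: str,
    *,
    context: ModelContext | None = None,
    freq_mode: str = "observed",
    init: SiteClassFit | None = None,
) -> SiteClassFit:
    """Fit M1a, Model A, or the omega2 = 1 null Model A.

    Model A variants require a non-empty foreground branch set.  Warm
    starting from a nested fit keeps the likelihood orderings
    lnL(ModelA) >= lnL(ModelA_fixed) >= ... numerically honest.
    """
    if model not in ("M1a", "ModelA", "ModelA_fixed"):
        raise ValueError(f"unknown site model {model!r}")
    if model != "M1a" and not foreground:
        raise ValueError("Model A needs a foreground branch set")
    ctx = context or ModelContext(aln, tree, freq_mode)
    B = ctx.n_branches
    counts = ctx.engine.counts
    foreground = set(foreground)

    is_m1a = model == "M1a"
    free_w2 = model == "ModelA"

    # x = [log t (B), log kappa, mix logits (1 or 2), logit w0, (log(w2-1))]
    def unpack(x):
        lengths = np.exp(x[:B])
        kappa = float(np.exp(x[B]))
        if is_m1a:
            a = x[B + 1]
            p0 = 1.0 / (1.0 + math.exp(-a))
            weights = np.array([p0, 1.0 - p0])
            w0 = _W0_EPS + (1.0 - 2 * _W0_EPS) / (1.0 + math.exp(-x[B + 2]))
            w2 = 1.0
        else:
            p0, p1, p2a, p2b = _model_a_weights(x[B + 1], x[B + 2])
            weights = np.array([p0, p1, p2a, p2b])
            w0 = _W0_EPS + (1.0 - 2 * _W0_EPS) / (1.0 + math.exp(-x[B + 3]))
            w2 = 1.0 + math.exp(x[B + 4]) if free_w2 else 1.0
            w2 = min(w2, OMEGA_CAP)
        return lengths, kappa, weights, w0, w2

    def negloglik(x):
        lengths, kappa, weights, w0, w2 = unpack(x)
        scale = _mixture_scale(ctx, kappa, weights, w0)
        class_omegas = [(w0, w0), (1.0, 1.0)]
        if not is_m1a:
            class_omegas += [(w0, w2), (1.0, w2)]
        stacked = _stacked_class_logliks(
            ctx, foreground, kappa, lengths, class_omegas, scale
        )
        return -_mixture_lnl(weights, list(stacked), counts)

    def logit(p):
        p = min(max(p, 1e-9), 1 - 1e-9)
        return math.log(p / (1 - p))

    starts = []
    if init is not None:
        lengths0 = np.log(np.clip(init.branch_lengths_hat, 1e-7, 20.0))
        k0 = math.log(init.kappa_hat)
        w0_logit = logit((init.omega0 - _W0_EPS) / (1 - 2 * _W0_EPS))
        if is_m1a:
            p0 = init.p0 + init.p2a
            starts.append(np.concatenate([lengths0, [k0, logit(p0), w0_logit]]))
        else:
            # shave a touch of mass into the selected classes when warm
            # starting from a model without them
            shrink = 0.9 if init.p2a + init.p2b < 1e-6 else 1.0
            p0 = max(init.p0 * shrink, 1e-4)
            p1 = max(init.p1 * shrink, 1e-4)
            rest = max(1.0 - p0 - p1, 1e-4)
            a = math.log(p0 / rest)
            bb = math.log(p1 / rest)
            x0 = [k0, a, bb, w0_logit]
            if free_w2:
                if init.omega2 > 1.0 + 1e-6:
                    w2_starts = (init.omega2,)
                else:
                    w2_starts = (2.5,)
                for w2 in w2_starts:
                    starts.append(
                        np.concatenate([lengths0, x0 + [math.log(w2 - 1.0)]])
                    )
            else:
                starts.append(np.concatenate([lengths0, x0]))
    else:
        lengths0 = np.log(np.clip(ctx.tree.branch_lengths, 1e-3, 19.0))
        k0 = math.log(2.0)
        if is_m1a:
            starts.append(np.concatenate([lengths0, [k0, logit(0.7), logit(0.1)]]))
        else:
            base = [k0, math.log(0.6 / 0.1), math.log(0.3 / 0.1), logit(0.1)]
            if free_w2:
                for w2 in (1.5, 5.0):
                    starts.append(
                        np.concatenate([lengths0, base + [math.log(w2 - 1.0)]])
                    )
            else:
                starts.append(np.concatenate([lengths0, base]))

    n_mix = 2 if is_m1a else 3
    bounds = (
        [_LOG_T_BOUNDS] * B
        + [_LOG_K_BOUNDS]
        + [(-_MIX_BOUND, _MIX_BOUND)] * (n_mix - 1)
        + [(-_MIX_BOUND, _MIX_BOUND)]  # w0 logit
    )
    if free_w2:
        bounds += [(math.log(1e-6), math.log(OMEGA_CAP - 1.0))]

    best = None
    for x0 in starts:
        res = scipy.optimize.minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res

    lengths, kappa, weights, w0, w2 = unpack(best.x)
    if is_m1a:
        p0, p1, p2a, p2b = weights[0], weights[1], 0.0, 0.0
        npar = B + 1 + 2  # B lengths, kappa, (p0, w0)
    else:
        p0, p1, p2a, p2b = weights
        npar = B + 1 + 3 + (1 if free_w2 else 0)  # + (p0, p1, w0) [, w2]
    return SiteClassFit(
        model=model,
        lnL=-float(best.fun),
        np=npar,
        p0=float(p0),
        p1=float(p1),
        p2a=float(p2a),
        p2b=float(p2b),
        omega0=float(w0),
        omega2=float(w2),
        kappa_hat=kappa,
        branch_lengths_hat=lengths,
        converged=bool(best.success),
        extra={"foreground": sorted(foreground)},
    )


def branch_site_tests(
    aln: CodonAlignment | None,
    tree: PhyloTree | None,
    foreground: set[int],
    *,
    context: ModelContext | None = None,
    freq_mode: str = "observed",
) -> dict:
    """Run tests 1 and 2 for one foreground branch set.

    Returns ``{"test1": (stat, p, df), "test2": (stat, p, df), "fits":
    {model: SiteClassFit}}``.  Test 1 contrasts Model A with the site
    model M1a (df 2); test 2 contrasts Model A with its omega2 = 1 null
    (df 1).  Fits are chained as warm starts so the nesting inequalities
    hold numerically.
    """
    ctx = context or ModelContext(aln, tree, freq_mode)
    m1a = fit_site_model(None, None, set(), "M1a", context=ctx)
    # Model A warm-starts from M1a; this is both
    # faster than cold starts and guarantees the nesting numerically
    ma = fit_site_model(None, None, foreground, "ModelA", context=ctx, init=m1a)
    fixed = fit_site_model(
        None, None, foreground, "ModelA_fixed", context=ctx, init=ma
    )
    if fixed.lnL > ma.lnL:  # null beat the alternative: re-polish Model A
        repolish = fit_site_model(
            None, None, foreground, "ModelA", context=ctx, init=fixed
        )
        if repolish.lnL > ma.lnL:
            ma = repolish
    stat1, p1 = lrt(min(m1a.lnL, ma.lnL + 1e-9), ma.lnL, df=2)
    stat2, p2 = lrt(min(fixed.lnL, ma.lnL + 1e-9), ma.lnL, df=1)
    return {
        "test1": (stat1, p1, 2),
        "test2": (stat2, p2, 1),
        "fits": {"M1a": m1a, "ModelA": ma, "ModelA_fixed": fixed},
    }


# ---------------------------------------------------------------------------
# Bayes empirical Bayes
# ---------------------------------------------------------------------------


def _beb_grids(cap: float = OMEGA_CAP):
    # 10-division triangle on (p0, p1), midpoints
    p_grid = [
        ((i + 0.5) / 10.0, (j + 0.5) / 10.0)
        for i in range(10)
        for j in range(10)
        if (i + 0.5) / 10.0 + (j + 0.5) / 10.0 < 1.0
    ]
    w0_grid = [(i + 0.5) / 10.0 for i in range(10)]
    # log-uniform midpoints on (1, cap)
    w2_grid = [float(np.exp((i + 0.5) / 10.0 * np.log(cap))) for i in range(10)]
    return p_grid, w0_grid, w2_grid


def beb_sites(
    aln: CodonAlignment | None,
    tree: PhyloTree | None,
    foreground: set[int],
    fit: SiteClassFit,
    *,
    context: ModelContext | None = None,
    freq_mode: str = "observed",
    threshold: float = 0.95,
) -> BEBReport:
    """Bayes-empirical-Bayes identification of positively selected sites.

    The posterior of membership in classes 2a+2b is averaged over a
    uniform prior grid: the 10-division triangle on (p0, p1), 10 points on
    omega0 in (0, 1), and 10 log-spaced points on omega2 in (1, cap);
    kappa and branch lengths stay at their MLEs.  Sites with posterior
    above ``threshold`` are reported with 1-based position and the first
    (reference) sequence's residue.
    """
    ctx = context or ModelContext(aln, tree, freq_mode)
    foreground = set(foreground)
    counts = ctx.engine.counts
    kappa, lengths = fit.kappa_hat, fit.branch_lengths_hat
    p_grid, w0_grid, w2_grid = _beb_grids()

    # rate units are pinned at the MLE: grid likelihoods reuse the fitted
    # model's scale, consistent with branch lengths held at their MLEs
    scale = _mixture_scale(
        ctx, kappa, np.array(fit.proportions), fit.omega0
    )

    l1 = _class_site_logliks(ctx, foreground, kappa, lengths, 1.0, 1.0, scale)
    l0 = {
        w0: _class_site_logliks(ctx, foreground, kappa, lengths, w0, w0, scale)
        for w0 in w0_grid
    }
    l2b = {
        w2: _class_site_logliks(ctx, foreground, kappa, lengths, 1.0, w2, scale)
        for w2 in w2_grid
    }
    l2a = {
        (w0, w2): _class_site_logliks(ctx, foreground, kappa, lengths, w0, w2, scale)
        for w0 in w0_grid
        for w2 in w2_grid
    }

    n_pat = ctx.engine.n_patterns
    post_num = np.zeros(n_pat)  # sum over grid of weight * P(2a|2b at site)
    marg = []  # log marginal per grid point
    combos = []
    for w0 in w0_grid:
        for w2 in w2_grid:
            stackA = np.stack([l0[w0], l1, l2a[(w0, w2)], l2b[w2]])
            for p0, p1 in p_grid:
                rest = 1.0 - p0 - p1
                denom = p0 + p1
                weights = np.array(
                    [p0, p1, rest * p0 / denom, rest * p1 / denom]
                )
                logw = np.log(weights)[:, None]
                site_log = logsumexp(stackA + logw, axis=0)
                sel_log = logsumexp(stackA[2:] + logw[2:], axis=0)
                marg.append(counts @ site_log)
                combos.append((sel_log, site_log))
    marg = np.array(marg)
    grid_logpost = marg - logsumexp(marg)  # uniform prior cancels
    for lw, (sel_log, site_log) in zip(grid_logpost, combos):
        post_num += np.exp(lw) * np.exp(sel_log - site_log)

    per_site = ctx.engine.expand(post_num)
    residues = ctx.aln.translate()[0]
    flagged = [
        (i + 1, residues[i], float(per_site[i]))
        for i in range(len(per_site))
        if per_site[i] > threshold
    ]
    return BEBReport(posterior=per_site, flagged_sites=flagged, threshold=threshold)
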