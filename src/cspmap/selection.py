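"""Likelihood-ratio selection tests on 3-taxon codon alignments.

Implements maximum-likelihood fitting of nested codon models on a species
trio and the lineage tests built from them:

* **M0** (one-ratio): a single dN/dS ratio omega on all branches.
* **free-ratio**: an independent omega per branch (df = 2 vs M0 on a trio).
* **branch**: one omega for a designated foreground branch, one shared by
  the background branches (df = 1 vs M0).  A significant test with
  omega_fg > omega_bg is classified as lineage-specific *acceleration*,
  omega_fg < omega_bg as *deceleration*.
* **branch-site model A**: four site classes -- omega0 (<1) everywhere;
  omega=1 everywhere; omega2 on the foreground with omega0 background;
  omega2 on the foreground with omega=1 background -- with mixture
  proportions p0, p1 and derived 2a/2b shares.  The positive-selection test
  compares model A against the same model with omega2 fixed to 1 (df = 1),
  so a significant result reflects omega > 1 on the foreground rather than
  a mere relaxation of constraint.

All fits maximise the likelihood over branch lengths, kappa and the model's
omega/proportion parameters by bounded quasi-Newton optimisation with
seeded random restarts; omega is capped at 999 and reported at the cap when
the optimiser hits it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .codonmodel import (
    CodonAlignment,
    CodonQ,
    PhyloTree,
    SENSE_CODONS,
    STOP_CODONS,
    CODON_INDEX,
    f3x4_frequencies,
    rate_coefficients,
    star_site_likelihoods,
)

__all__ = [
    "OMEGA_MAX",
    "validate_alignment",
    "log_likelihood",
    "fit_model",
    "lrt",
    "branch_tests",
    "branch_site_test",
    "CodonModelFit",
    "LRTResult",
    "BranchTestReport",
    "BranchSiteResult",
    "MODELS",
]

MODELS = ("M0", "free_ratio", "branch", "branch_site_A", "branch_site_null")

OMEGA_MIN, OMEGA_MAX = 1e-4, 999.0
T_MIN, T_MAX = 1e-7, 50.0
KAPPA_MIN, KAPPA_MAX = 1e-2, 100.0
_LOGIT_BOUND = 30.0


class AlignmentError(ValueError):
    """Raised for alignments that cannot form a valid codon matrix."""


def validate_alignment(records: Sequence[Tuple[str, str]]) -> CodonAlignment:
    """Build a validated codon alignment from three (name, sequence) pairs.

    Sequences must be equal-length and in frame.  Codon columns containing a
    gap or ambiguity character in any taxon are removed (cleandata-style); a
    shared terminal stop codon column is stripped; any remaining internal
    stop codon is an error naming its position.
    """
    recs = [(str(n), str(s).upper().replace("U", "T")) for n, s in records]
    if len(recs) != 3:
        raise AlignmentError(f"need exactly 3 sequences, got {len(recs)}")
    names = [n for n, _ in recs]
    if len(set(names)) != 3:
        raise AlignmentError("duplicate taxon names")
    lengths = {len(s) for _, s in recs}
    if len(lengths) != 1:
        raise AlignmentError("sequences have unequal lengths")
    (length,) = lengths
    if length % 3:
        raise AlignmentError(f"alignment length {length} not divisible by 3")

    n_col = length // 3
    cols = [[s[3 * i:3 * i + 3] for _, s in recs] for i in range(n_col)]
    clean = [c for c in cols if all(set(codon) <= set("ACGT") for codon in c)]
    removed = n_col - len(clean)
    if clean and any(codon in STOP_CODONS for codon in clean[-1]):
        clean = clean[:-1]   # shared terminal stop column
    for i, col in enumerate(clean):
        for name, codon in zip(names, col):
            if codon in STOP_CODONS:
                raise AlignmentError(
                    f"internal stop codon {codon} in {name} at codon {i + 1}")
    if not clean:
        raise AlignmentError("no usable codon columns after filtering")
    idx = np.array([[CODON_INDEX[col[t]] for col in clean] for t in range(3)],
                   dtype=np.int64)
    return CodonAlignment(taxa=names, codons=idx, removed_columns=removed)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

class _QCache:
    """Eigendecomposition cache keyed on (kappa, omega), pi fixed."""

    def __init__(self, pi: np.ndarray):
        self.pi = pi
        self._store: Dict[Tuple[float, float], CodonQ] = {}

    def get(self, kappa: float, omega: float) -> CodonQ:
        key = (float(kappa), float(omega))
        if key not in self._store:
            if len(self._store) > 256:
                self._store.clear()
            self._store[key] = CodonQ(kappa, omega, self.pi)
        return self._store[key]


def _mixture_loglik(patterns: np.ndarray, counts: np.ndarray,
                    t: np.ndarray, kappa: float,
                    class_omegas: Sequence[Tuple[float, float, float]],
                    class_props: Sequence[float],
                    cache: _QCache) -> float:
    """Log-likelihood of a (possibly one-class) site mixture on the star tree.

    Branch lengths are expected substitutions per codon averaged over site
    classes: per-omega generators are individually normalised, so a class
    with omega above the branch's mixture-average omega runs at a
    proportionally higher rate (effective length t * (A+B*w)/(A+B*wbar),
    with rate(w) = A + B*w linear in omega).  For one-class models the
    multiplier is exactly 1.
    """
    A, B = rate_coefficients(kappa, cache.pi)
    wbar = [sum(p * w[b] for p, w in zip(class_props, class_omegas))
            for b in range(3)]
    pmat: Dict[Tuple[float, int], np.ndarray] = {}
    site_L = np.zeros(patterns.shape[1])
    for prop, omegas in zip(class_props, class_omegas):
        if prop <= 0:
            continue
        ps = []
        for b in range(3):
            t_eff = t[b] * (A + B * omegas[b]) / (A + B * wbar[b])
            key = (float(omegas[b]), b)
            if key not in pmat:
                pmat[key] = cache.get(kappa, omegas[b]).transition_probs(t_eff)
            ps.append(pmat[key])
        site_L += prop * star_site_likelihoods(ps, cache.pi, patterns)
    if np.any(site_L <= 0.0) or not np.all(np.isfinite(site_L)):
        return -np.inf
    return float(counts @ np.log(site_L))


def log_likelihood(alignment: CodonAlignment, tree: PhyloTree, kappa: float,
                   omega, pi: Optional[np.ndarray] = None) -> float:
    """Log-likelihood of the alignment under given parameters.

    ``omega`` may be a scalar (shared ratio) or a length-3 sequence of
    per-branch ratios ordered as ``tree.taxa``.  Codon frequencies default
    to F3x4 estimated from the alignment.
    """
    if pi is None:
        pi = f3x4_frequencies(alignment.codons)
    omegas = (float(omega),) * 3 if np.isscalar(omega) else tuple(float(w) for w in omega)
    if len(omegas) != 3:
        raise ValueError("omega must be scalar or length-3")
    patterns, counts = alignment.patterns()
    order = [alignment.taxa.index(t) for t in tree.taxa]
    cache = _QCache(np.asarray(pi, float))
    return _mixture_loglik(patterns[order], counts, tree.branch_lengths,
                           float(kappa), [omegas], [1.0], cache)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class CodonModelFit:
    model: str
    log_likelihood: float
    branch_lengths: np.ndarray           # ordered as ``taxa``
    kappa: float
    omegas: Dict[str, float]
    proportions: Dict[str, float] = field(default_factory=dict)
    taxa: List[str] = field(default_factory=list)
    foreground: Optional[str] = None
    converged: bool = True
    n_evals: int = 0

    @property
    def omega_capped(self) -> bool:
        return any(w >= OMEGA_MAX * (1 - 1e-6) for w in self.omegas.values())


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return math.log(p / (1 - p))


def _model_spec(model: str, fg: Optional[int]):
    """Bounds and (classes, props) builders for each model's parameter tail.

    The shared head of the parameter vector is log t (3) + log kappa.
    """
    lo_w, hi_w = math.log(OMEGA_MIN), math.log(OMEGA_MAX)
    if model in ("branch", "branch_site_A", "branch_site_null") and fg is None:
        raise ValueError(f"model {model} needs a designated foreground branch")

    def bg_tuple(w_fg: float, w_bg: float) -> Tuple[float, float, float]:
        out = [w_bg] * 3
        out[fg] = w_fg
        return tuple(out)

    if model == "M0":
        bounds = [(lo_w, hi_w)]

        def classes(tail):
            w = math.exp(tail[0])
            return [(w, w, w)], [1.0], {"omega": w}, {}
    elif model == "free_ratio":
        bounds = [(lo_w, hi_w)] * 3

        def classes(tail):
            ws = tuple(math.exp(v) for v in tail)
            return [ws], [1.0], {f"omega_{b}": w for b, w in enumerate(ws)}, {}
    elif model == "branch":
        bounds = [(lo_w, hi_w)] * 2

        def classes(tail):
            w_fg, w_bg = (math.exp(v) for v in tail)
            return ([bg_tuple(w_fg, w_bg)], [1.0],
                    {"omega_fg": w_fg, "omega_bg": w_bg}, {})
    elif model in ("branch_site_A", "branch_site_null"):
        free_w2 = model == "branch_site_A"
        bounds = [(lo_w, 0.0)]                       # omega0 in (0, 1]
        if free_w2:
            bounds.append((0.0, hi_w))               # omega2 in [1, 999]
        bounds += [(-_LOGIT_BOUND, _LOGIT_BOUND)] * 2

        def classes(tail):
            w0 = math.exp(tail[0])
            pos = 1
            if free_w2:
                w2 = math.exp(tail[pos])
                pos += 1
            else:
                w2 = 1.0
            s_mix = _sigmoid(tail[pos])       # p0 + p1
            s_ratio = _sigmoid(tail[pos + 1])  # p0 / (p0 + p1)
            p0 = s_mix * s_ratio
            p1 = s_mix * (1 - s_ratio)
            p2a = (1 - s_mix) * s_ratio
            p2b = (1 - s_mix) * (1 - s_ratio)
            cls = [(w0, w0, w0), (1.0, 1.0, 1.0),
                   bg_tuple(w2, w0), bg_tuple(w2, 1.0)]
            return (cls, [p0, p1, p2a, p2b],
                    {"omega0": w0, "omega2": w2},
                    {"p0": p0, "p1": p1, "p2a": p2a, "p2b": p2b})
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return bounds, classes


def _initial_branch_lengths(alignment: CodonAlignment, order: Sequence[int]) -> np.ndarray:
    """Additive starting lengths from pairwise codon p-distances."""
    c = alignment.codons[list(order)]
    d = np.zeros((3, 3))
    for i in range(3):
        for j in range(i + 1, 3):
            d[i, j] = d[j, i] = np.mean(c[i] != c[j])
    t = np.array([(d[0, 1] + d[0, 2] - d[1, 2]) / 2,
                  (d[0, 1] + d[1, 2] - d[0, 2]) / 2,
                  (d[0, 2] + d[1, 2] - d[0, 1]) / 2])
    return np.clip(t, 0.01, 2.0)


def _warm_tail(model: str, warm: CodonModelFit, fg: Optional[int]) -> Optional[List[float]]:
    """Map a fitted nested model onto this model's tail parameters."""
    w = warm.omegas
    try:
        if model == "M0" and "omega" in w:
            return [math.log(w["omega"])]
        if model == "branch" and "omega" in w:
            return [math.log(w["omega"])] * 2
        if model == "free_ratio":
            if "omega" in w:
                return [math.log(w["omega"])] * 3
            if "omega_fg" in w:
                ws = [w["omega_bg"]] * 3
                ws[fg] = w["omega_fg"]
                return [math.log(x) for x in ws]
        if model == "branch_site_A" and warm.model == "branch_site_null":
            p = warm.proportions
            s_mix = p["p0"] + p["p1"]
            s_ratio = p["p0"] / s_mix if s_mix > 0 else 0.5
            return [math.log(max(w["omega0"], OMEGA_MIN)), 0.0,
                    _logit(s_mix), _logit(s_ratio)]
    except (KeyError, ValueError):
        return None
    return None


def fit_model(alignment: CodonAlignment, tree: PhyloTree, model: str,
              n_starts: int = 3, seed: int = 0,
              pi: Optional[np.ndarray] = None,
              warm: Optional[CodonModelFit] = None,
              maxiter: int = 400) -> CodonModelFit:
    """Maximum-likelihood fit of one codon model.

    Optimises log branch lengths, log kappa and the model's omega /
    proportion parameters with L-BFGS-B from ``n_starts`` seeded starting
    points (a distance-based heuristic plus random perturbations); when a
    nested fit is supplied via ``warm`` its solution seeds an extra start,
    which also guarantees the nesting inequality in practice.
    """
    if pi is None:
        pi = f3x4_frequencies(alignment.codons)
    pi = np.asarray(pi, float)
    order = [alignment.taxa.index(t) for t in tree.taxa]
    patterns, counts = alignment.patterns()
    patterns = patterns[order]
    fg = tree.foreground_index if tree.foreground is not None else None
    tail_bounds, make_classes = _model_spec(model, fg)
    bounds = [(math.log(T_MIN), math.log(T_MAX))] * 3 + \
             [(math.log(KAPPA_MIN), math.log(KAPPA_MAX))] + tail_bounds
    cache = _QCache(pi)
    n_evals = [0]

    def objective(x: np.ndarray) -> float:
        n_evals[0] += 1
        t = np.exp(x[:3])
        kappa = math.exp(x[3])
        class_omegas, props, _, _ = make_classes(x[4:])
        ll = _mixture_loglik(patterns, counts, t, kappa, class_omegas, props, cache)
        return 1e12 if not np.isfinite(ll) else -ll

    t0 = np.log(_initial_branch_lengths(alignment, order))
    default_tails = {
        "M0": [math.log(0.4)],
        "free_ratio": [math.log(0.4)] * 3,
        "branch": [math.log(0.6), math.log(0.3)],
        "branch_site_A": [math.log(0.2), math.log(2.0), _logit(0.85), _logit(0.8)],
        "branch_site_null": [math.log(0.2), _logit(0.85), _logit(0.8)],
    }
    x0 = np.concatenate([t0, [math.log(2.0)], default_tails[model]])
    starts = [x0]
    if warm is not None:
        tail = _warm_tail(model, warm, fg)
        if tail is not None:
            tw = np.log(np.clip(warm.branch_lengths, T_MIN, T_MAX))
            starts.append(np.concatenate([tw, [math.log(warm.kappa)], tail]))
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    while len(starts) < max(n_starts, len(starts)):
        starts.append(np.clip(x0 + rng.normal(0, 0.7, size=len(x0)), lo, hi))

    best = None
    converged = False
    for s in starts:
        res = optimize.minimize(objective, s, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "maxfun": 4 * maxiter})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success) or converged
    x = best.x
    t_hat = np.exp(x[:3])
    kappa_hat = math.exp(x[3])
    _, props, omegas, prop_names = make_classes(x[4:])
    return CodonModelFit(model=model, log_likelihood=-float(best.fun),
                         branch_lengths=t_hat, kappa=kappa_hat, omegas=omegas,
                         proportions=prop_names, taxa=list(tree.taxa),
                         foreground=tree.foreground, converged=converged,
                         n_evals=n_evals[0])


# ---------------------------------------------------------------------------
# Likelihood-ratio tests
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    two_delta_ell: float
    df: int
    p_value: float
    null_model: str = ""
    alt_model: str = ""


def lrt(null_fit: CodonModelFit, alt_fit: CodonModelFit, df: int) -> LRTResult:
    """Likelihood-ratio test of nested fits: 2(l_alt - l_null) vs chi2(df),
    with the statistic clamped at zero against optimiser jitter."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = max(0.0, 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood))
    return LRTResult(two_delta_ell=stat, df=df,
                     p_value=float(stats.chi2.sf(stat, df)),
                     null_model=null_fit.model, alt_model=alt_fit.model)


@dataclass
class BranchTestReport:
    fits: Dict[str, CodonModelFit]
    lrt_free_vs_m0: LRTResult
    lrt_branch_vs_m0: LRTResult
    classification: str                  # accelerated | decelerated | unchanged
    foreground: str


def branch_tests(alignment: CodonAlignment, tree: PhyloTree, alpha: float = 0.05,
                 n_starts: int = 3, seed: int = 0,
                 pi: Optional[np.ndarray] = None) -> BranchTestReport:
    """Lineage rate-variation tests: free-ratio vs M0 (df=2) and the
    foreground branch model vs M0 (df=1), with the foreground classified as
    accelerated / decelerated / unchanged."""
    m0 = fit_model(alignment, tree, "M0", n_starts=n_starts, seed=seed, pi=pi)
    br = fit_model(alignment, tree, "branch", n_starts=n_starts,
                   seed=seed + 2, pi=pi, warm=m0)
    # warm the free-ratio fit from the branch fit so the likelihood chain
    # M0 <= branch <= free-ratio holds by construction
    free = fit_model(alignment, tree, "free_ratio", n_starts=n_starts,
                     seed=seed + 1, pi=pi, warm=br)
    lrt_free = lrt(m0, free, df=len(tree.taxa) - 1)
    lrt_branch = lrt(m0, br, df=1)
    if lrt_branch.p_value < alpha:
        classification = ("accelerated" if br.omegas["omega_fg"] > br.omegas["omega_bg"]
                          else "decelerated")
    else:
        classification = "unchanged"
    return BranchTestReport(fits={"M0": m0, "free_ratio": free, "branch": br},
                            lrt_free_vs_m0=lrt_free, lrt_branch_vs_m0=lrt_branch,
                            classification=classification,
                            foreground=tree.foreground)


@dataclass
class BranchSiteResult:
    null_fit: CodonModelFit
    alt_fit: CodonModelFit
    lrt: LRTResult
    omega2: float
    omega2_capped: bool
    foreground: str


def branch_site_test(alignment: CodonAlignment, tree: PhyloTree,
                     n_starts: int = 3, seed: int = 0,
                     pi: Optional[np.ndarray] = None) -> BranchSiteResult:
    """Positive-selection test: branch-site model A against its omega2=1
    null (df=1).  A significant result supports a site class with omega > 1
    on the foreground branch; omega2 is reported at the 999 cap when the
    optimiser pins it there."""
    null = fit_model(alignment, tree, "branch_site_null", n_starts=n_starts,
                     seed=seed, pi=pi)
    alt = fit_model(alignment, tree, "branch_site_A", n_starts=n_starts,
                    seed=seed + 1, pi=pi, warm=null)
    res = lrt(null, alt, df=1)
    w2 = alt.omegas["omega2"]
    return BranchSiteResult(null_fit=null, alt_fit=alt, lrt=res, omega2=w2,
                            omega2_capped=w2 >= OMEGA_MAX * (1 - 1e-6),
                            foreground=tree.foreground)
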