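"""Synthetic inputs with the statistical structure the analysis assumes.

Every pipeline stage can be exercised end to end without any external data:
this module generates double-mating trial tables (beta-binomial paternity
with line, block and fecundity structure), introgression panels with a
planted two-locus epistatic breakdown rule plus suppressor/extra-locus
exceptions, qPCR Ct tables around known between-species fold differences,
codon alignments evolved under one-ratio / branch / branch-site regimes,
and gene annotation tables with planted candidates.  Each generator takes a
seed and is byte-reproducible; each returns its planted truth alongside the
table so recovery can be checked.

Defaults emulate the study design the package targets: ~60 introgression
lines assayed over nine blocks with ~30 females per line, a heterospecific
baseline second male siring ~5% of progeny against ~80% for a conspecific-
like male, a weak positive correlation (0.119) between paternity share and
post-remating fecundity, and about a third of females lost to failed first
or second matings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .bands import CytoBand, CytoInterval, parse_band
from .codonmodel import (
    CodonAlignment,
    CodonQ,
    N_CODONS,
    PhyloTree,
    SENSE_CODONS,
    rate_coefficients,
    uniform_frequencies,
)

__all__ = [
    "MatingSimConfig",
    "PanelSimConfig",
    "CodonSimConfig",
    "gen_mating_trials",
    "gen_introgression_panel",
    "simulate_codon_alignment",
    "gen_qpcr_table",
    "gen_gene_annotation_table",
    "MALE_REPRODUCTIVE_TERMS",
]


# ---------------------------------------------------------------------------
# Double-mating paternity trials
# ---------------------------------------------------------------------------

@dataclass
class MatingSimConfig:
    """Study-design parameters for the paternity-trial generator.

    ``baseline_p2`` is the heterospecific-like mean second-male share and
    ``normal_p2`` the conspecific-like mean; ``p2_dispersion`` is the beta
    concentration of female-level variation around a line's mean (inf =
    no female-level noise).  Fecundity is negative-binomial
    (``fecundity_dispersion`` = size; inf = fixed at the mean) and is
    coupled to paternity through a shared Gaussian latent factor with
    Pearson strength ``fecundity_p2_corr``.  Block effects are additive
    i.i.d. Normal(0, ``block_sd``) on the arcsine-transformed scale.
    """

    n_lines: int = 60
    females_per_line: int = 30
    n_blocks: int = 9
    baseline_p2: float = 0.05
    normal_p2: float = 0.80
    p2_dispersion: float = 12.0
    fecundity_mean: float = 45.0
    fecundity_dispersion: float = 6.0
    fecundity_p2_corr: float = 0.119
    block_sd: float = 0.05
    n_baseline_lines: int = 12
    first_mating_fail_rate: float = 0.20
    second_mating_fail_rate: float = 0.18
    vial1_mean: float = 25.0
    baseline_sample_id: str = "MAU"
    baseline_sample_size: int = 30
    seed: int = 0

    def validate(self) -> None:
        for name in ("baseline_p2", "normal_p2"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for name in ("n_lines", "females_per_line", "n_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("p2_dispersion", "fecundity_dispersion", "fecundity_mean"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not -1.0 <= self.fecundity_p2_corr <= 1.0:
            raise ValueError("fecundity_p2_corr must be in [-1, 1]")
        if self.block_sd < 0:
            raise ValueError("block_sd must be >= 0")
        for name in ("first_mating_fail_rate", "second_mating_fail_rate"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 <= self.n_baseline_lines <= self.n_lines:
            raise ValueError("n_baseline_lines must be within [0, n_lines]")


def _beta_ppf(u: np.ndarray, mean: float, conc: float) -> np.ndarray:
    if not math.isfinite(conc):
        return np.full_like(u, mean)
    a = mean * conc
    b = (1.0 - mean) * conc
    return stats.beta.ppf(u, a, b)


def _nbinom_ppf(u: np.ndarray, mean: float, size: float) -> np.ndarray:
    if not math.isfinite(size):
        return np.full_like(u, round(mean))
    p = size / (size + mean)
    return stats.nbinom.ppf(u, size, p)


def gen_mating_trials(config: MatingSimConfig,
                      baseline_line_ids: Optional[Sequence[str]] = None
                      ) -> Tuple[pd.DataFrame, Dict]:
    """Generate one row per doubly-mated female, plus the planted truth.

    A designated subset of lines (``baseline_line_ids`` or the first
    ``n_baseline_lines``) has mean P2 equal to ``baseline_p2``; the others
    have ``normal_p2``.  Female-level paternity is beta-binomial around the
    line mean shifted by the block effect on the arcsine scale; fecundity
    is negative-binomial, correlated with paternity via a shared Gaussian
    latent variable.  A configurable fraction of females fail the first or
    second mating (zero vial-1 marker progeny / zero vial-2+3 progeny) so
    the exclusion rules can be exercised.  An extra heterospecific baseline
    sample (line ``baseline_sample_id``) is appended for the baseline
    t-tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    line_ids = [f"IG{i + 1:02d}" for i in range(config.n_lines)]
    if baseline_line_ids is None:
        baseline_line_ids = line_ids[:config.n_baseline_lines]
    baseline_set = set(map(str, baseline_line_ids))
    unknown = baseline_set - set(line_ids)
    if unknown:
        raise ValueError(f"baseline_line_ids not in panel: {sorted(unknown)}")

    line_means = {lid: (config.baseline_p2 if lid in baseline_set else config.normal_p2)
                  for lid in line_ids}
    line_means[config.baseline_sample_id] = config.baseline_p2
    block_effects = rng.normal(0.0, config.block_sd, size=config.n_blocks)

    rho = config.fecundity_p2_corr
    rows: List[Dict] = []
    female = 0
    sim_lines = line_ids + [config.baseline_sample_id]
    for lid in sim_lines:
        n_f = (config.baseline_sample_size if lid == config.baseline_sample_id
               else config.females_per_line)
        blocks = rng.integers(0, config.n_blocks, size=n_f)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n_f)
        u_p2, u_fec = stats.norm.cdf(z[:, 0]), stats.norm.cdf(z[:, 1])
        tp2_mean = np.arcsin(math.sqrt(line_means[lid])) + block_effects[blocks]
        mean_p = np.clip(np.sin(np.clip(tp2_mean, 0.0, math.pi / 2)) ** 2,
                         1e-4, 1 - 1e-4)
        fail1 = rng.random(n_f) < config.first_mating_fail_rate
        fail2 = rng.random(n_f) < config.second_mating_fail_rate
        vial1 = 1 + rng.poisson(config.vial1_mean, size=n_f)
        vial1[fail1] = 0
        for i in range(n_f):
            female += 1
            p2_f = float(_beta_ppf(np.array([u_p2[i]]), float(mean_p[i]),
                                   config.p2_dispersion)[0])
            fec = int(_nbinom_ppf(np.array([u_fec[i]]), config.fecundity_mean,
                                  config.fecundity_dispersion)[0])
            if fail2[i]:
                wt, eb = 0, 0
            else:
                wt = int(rng.binomial(fec, p2_f)) if fec > 0 else 0
                eb = fec - wt
            rows.append({"female_id": f"F{female:05d}", "line_id": lid,
                         "block": int(blocks[i]) + 1, "vial1_ebony": int(vial1[i]),
                         "vial23_wildtype": wt, "vial23_ebony": eb})
    trials = pd.DataFrame(rows)
    truth = {"baseline_line_ids": sorted(baseline_set),
             "line_means": line_means,
             "baseline_sample_id": config.baseline_sample_id}
    return trials, truth


# ---------------------------------------------------------------------------
# Introgression panel with planted epistasis
# ---------------------------------------------------------------------------

# Default 5-region tiling of the mapped chromosome span, with the co-required
# loci (regions 2 and 4) matching the 77B-84B and 88B-92E map ranges.
DEFAULT_REGION_BOUNDS = ("73A1", "77A20", "84B10", "88A20", "92E10", "100F20")


@dataclass
class PanelSimConfig:
    """Layout of the synthetic introgression panel.

    ``region_bounds`` are k+1 strictly increasing band coordinates tiling
    the mapped span into k regions (region r runs from just after bound r-1
    to bound r); interior bounds need explicit sub-bands.  Breakdown is
    planted for lines whose segment covers every region in
    ``corequired_set``, then flipped for ``suppressor_lines`` covering
    lines and ``extra_locus_lines`` non-covering lines.
    """

    region_bounds: Sequence[str] = DEFAULT_REGION_BOUNDS
    corequired_set: Set[int] = field(default_factory=lambda: {2, 4})
    n_lines: int = 60
    suppressor_lines: int = 0
    extra_locus_lines: int = 0
    seed: int = 0

    @property
    def n_regions(self) -> int:
        return len(self.region_bounds) - 1

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ValueError("need at least two region bounds")
        bands = [parse_band(b) for b in self.region_bounds]
        keys = [b.key_start() for b in bands]
        if keys != sorted(set(keys)):
            raise ValueError("region bounds must be strictly increasing")
        if not self.corequired_set:
            raise ValueError("corequired_set must be non-empty")
        bad = {r for r in self.corequired_set if not 1 <= r <= self.n_regions}
        if bad:
            raise ValueError(f"corequired_set references nonexistent regions: {sorted(bad)}")
        if self.n_lines < 1 or self.suppressor_lines < 0 or self.extra_locus_lines < 0:
            raise ValueError("line counts must be non-negative (n_lines >= 1)")

    def region_interval(self, r: int) -> CytoInterval:
        start = parse_band(self.region_bounds[r - 1])
        if r > 1:   # successor of the previous bound, sub-band + 1
            start = CytoBand(start.division, start.letter,
                             (start.subband or 1) + 1)
        return CytoInterval(start, parse_band(self.region_bounds[r]))


def _span_patterns(k: int) -> List[Tuple[int, int]]:
    """All contiguous region spans shorter than the whole map, ordered by
    (length, start): singles, adjacent pairs, triples, ..."""
    spans = [(i, j) for L in range(1, k) for i in range(1, k - L + 2)
             for j in [i + L - 1]]
    return spans


def gen_introgression_panel(config: PanelSimConfig,
                            line_means: Optional[Dict[str, float]] = None
                            ) -> Tuple[pd.DataFrame, Dict]:
    """Generate the line x interval table with planted breakdown flags.

    Lines cycle through every contiguous span pattern (single regions,
    adjacent pairs, triples, four-region spans, ...).  The planted flag is
    true iff the span covers every co-required region; the configured
    number of suppressor (covering, no breakdown) and extra-locus
    (breakdown, not covering) exceptions are then flipped at seeded random
    among eligible lines.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_regions
    spans = _span_patterns(k)
    req = set(config.corequired_set)

    rows = []
    for i in range(config.n_lines):
        lo, hi = spans[i % len(spans)]
        covers = req <= set(range(lo, hi + 1))
        interval = CytoInterval(config.region_interval(lo).start,
                                config.region_interval(hi).end)
        rows.append({"line_id": f"IG{i + 1:02d}",
                     "start_band": str(interval.start),
                     "end_band": str(interval.end),
                     "covers_corequired": covers,
                     "true_breakdown": covers})
    panel = pd.DataFrame(rows)

    covering = panel.index[panel["covers_corequired"]].to_numpy()
    non_covering = panel.index[~panel["covers_corequired"]].to_numpy()
    if config.suppressor_lines > len(covering):
        raise ValueError("more suppressor lines requested than covering lines")
    if config.extra_locus_lines > len(non_covering):
        raise ValueError("more extra-locus lines requested than non-covering lines")
    sup_idx = rng.choice(covering, size=config.suppressor_lines, replace=False) \
        if config.suppressor_lines else np.array([], dtype=int)
    ext_idx = rng.choice(non_covering, size=config.extra_locus_lines, replace=False) \
        if config.extra_locus_lines else np.array([], dtype=int)
    panel.loc[sup_idx, "true_breakdown"] = False
    panel.loc[ext_idx, "true_breakdown"] = True

    if line_means is not None:
        panel["mean_p2"] = panel["line_id"].map(line_means)
    truth = {
        "corequired_set": sorted(req),
        "suppressor_ids": sorted(panel.loc[sup_idx, "line_id"].tolist()),
        "extra_locus_ids": sorted(panel.loc[ext_idx, "line_id"].tolist()),
        "breakdown_ids": sorted(panel.loc[panel["true_breakdown"], "line_id"].tolist()),
        "region_intervals": {r: str(config.region_interval(r))
                             for r in range(1, k + 1)},
    }
    return panel.drop(columns=["covers_corequired"]), truth


# ---------------------------------------------------------------------------
# Codon-alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class CodonSimConfig:
    """Simulation regime for a 3-taxon codon alignment.

    ``omegas`` is model-dependent: ``{"omega": w}`` for one_ratio, per-taxon
    values for branch regimes (``{"omega_fg": ., "omega_bg": .}``), and
    ``{"omega0": ., "omega2": .}`` with class ``proportions`` (p0, p1) for
    branch_site.  Stop codons never occur: evolution runs on the 61-state
    sense-codon alphabet.
    """

    tree: PhyloTree = None
    model: str = "one_ratio"
    omegas: Dict[str, float] = field(default_factory=lambda: {"omega": 0.2})
    kappa: float = 2.0
    codon_freqs: Optional[np.ndarray] = None
    proportions: Tuple[float, float] = (0.7, 0.2)   # p0, p1 (branch_site only)
    n_codons: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.tree is None:
            raise ValueError("tree is required")
        if self.model not in ("one_ratio", "branch", "branch_site"):
            raise ValueError(f"unknown simulation model {self.model!r}")
        if self.kappa <= 0 or self.n_codons < 1:
            raise ValueError("kappa must be > 0 and n_codons >= 1")
        if any(w < 0 for w in self.omegas.values()):
            raise ValueError("omega values must be >= 0")
        if self.codon_freqs is not None:
            pi = np.asarray(self.codon_freqs, float)
            if pi.shape != (N_CODONS,) or abs(pi.sum() - 1) > 1e-8 or np.any(pi < 0):
                raise ValueError("codon_freqs must be a 61-vector over sense "
                                 "codons summing to 1")
        if self.model == "branch_site":
            p0, p1 = self.proportions
            if p0 < 0 or p1 < 0 or p0 + p1 > 1:
                raise ValueError("proportions must satisfy p0, p1 >= 0, p0+p1 <= 1")


def _sample_children(P: np.ndarray, parents: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P[parents], axis=1)
    u = rng.random(len(parents))
    return np.minimum((u[:, None] > cum).sum(axis=1), P.shape[1] - 1)


def simulate_codon_alignment(config: CodonSimConfig) -> CodonAlignment:
    """Evolve a root codon sequence along the three branches.

    The root is drawn from the stationary codon frequencies and each branch
    applies the transition probabilities of the regime's rate matrix; for
    branch_site each site is first assigned a class with model-A
    proportions.  No stop codons can ever be produced.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    pi = (uniform_frequencies() if config.codon_freqs is None
          else np.asarray(config.codon_freqs, float))
    n = config.n_codons
    fg = tree.foreground_index if tree.foreground is not None else 0

    if config.model == "one_ratio":
        w = config.omegas["omega"]
        class_omegas = [(w, w, w)]
        class_probs = [1.0]
    elif config.model == "branch":
        w_fg, w_bg = config.omegas["omega_fg"], config.omegas["omega_bg"]
        ws = [w_bg] * 3
        ws[fg] = w_fg
        class_omegas = [tuple(ws)]
        class_probs = [1.0]
    else:  # branch_site, model-A classes
        w0, w2 = config.omegas["omega0"], config.omegas["omega2"]
        p0, p1 = config.proportions
        p2 = 1.0 - p0 - p1
        denom = p0 + p1 if p0 + p1 > 0 else 1.0

        def fg_tuple(wf, wb):
            out = [wb] * 3
            out[fg] = wf
            return tuple(out)

        class_omegas = [(w0,) * 3, (1.0,) * 3, fg_tuple(w2, w0), fg_tuple(w2, 1.0)]
        class_probs = [p0, p1, p2 * p0 / denom, p2 * p1 / denom]

    site_class = rng.choice(len(class_probs), size=n, p=class_probs)
    root = rng.choice(N_CODONS, size=n, p=pi)
    seqs = np.zeros((3, n), dtype=np.int64)
    # Branch lengths are mixture-average expected substitutions per codon:
    # classes with omega above the branch average run proportionally faster.
    A, B = rate_coefficients(config.kappa, pi)
    pmats: Dict[Tuple[float, float], np.ndarray] = {}
    for b in range(3):
        t = float(tree.branch_lengths[b])
        wbar = sum(p * w[b] for p, w in zip(class_probs, class_omegas))
        for c in range(len(class_probs)):
            mask = site_class == c
            if not mask.any():
                continue
            w = class_omegas[c][b]
            t_eff = t * (A + B * w) / (A + B * wbar)
            key = (w, t_eff)
            if key not in pmats:
                pmats[key] = CodonQ(config.kappa, w, pi).transition_probs(t_eff)
            seqs[b, mask] = _sample_children(pmats[key], root[mask], rng)
    return CodonAlignment(taxa=list(tree.taxa), codons=seqs)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def gen_qpcr_table(genes: Sequence[str], true_folds: Sequence[float],
                   replicate_sd: float = 0.3, n_replicates: int = 2,
                   seed: int = 0, species: Tuple[str, str] = ("sim", "mau"),
                   base_reference_ct: float = 16.0) -> pd.DataFrame:
    """Ct table around known species-2/species-1 fold differences.

    Per species and replicate the reference Ct is Normal(base, sd) and the
    target Ct is reference + dCt, where the gene's species-2 dCt minus its
    species-1 dCt equals -log2(true_fold) plus Normal(0, sd) noise.  With
    ``replicate_sd=0`` the estimated folds are exact.
    """
    genes = list(map(str, genes))
    folds = np.asarray(list(true_folds), float)
    if len(genes) != len(folds):
        raise ValueError("genes and true_folds length mismatch")
    if np.any(folds <= 0):
        raise ValueError("true folds must be > 0")
    if n_replicates < 1 or replicate_sd < 0:
        raise ValueError("need n_replicates >= 1 and replicate_sd >= 0")
    rng = np.random.default_rng(seed)
    base_dct = rng.uniform(2.0, 8.0, size=len(genes))   # shared across species
    rows = []
    for gi, gene in enumerate(genes):
        for si, sp in enumerate(species):
            shift = 0.0 if si == 0 else -math.log2(folds[gi])
            for rep in range(1, n_replicates + 1):
                ct_ref = rng.normal(base_reference_ct, replicate_sd)
                dct = base_dct[gi] + shift + rng.normal(0.0, replicate_sd)
                rows.append({"gene": gene, "species": sp, "replicate": rep,
                             "ct_target": ct_ref + dct, "ct_reference": ct_ref})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene annotation tables
# ---------------------------------------------------------------------------

MALE_REPRODUCTIVE_TERMS = (
    "male reproductive system", "testis", "accessory gland",
    "sperm competition", "seminal fluid", "spermatogenesis",
)
_OTHER_TERMS = ("ovary", "brain", "midgut", "cuticle", "eye", "wing disc")


def _random_band_inside(interval: CytoInterval, rng: np.random.Generator) -> CytoBand:
    for _ in range(1000):
        division = int(rng.integers(interval.start.division, interval.end.division + 1))
        letter = "ABCDEF"[rng.integers(0, 6)]
        band = CytoBand(division, letter, int(rng.integers(1, 21)))
        if interval.contains_band(band):
            return band
    raise RuntimeError("could not sample a band inside the locus")


def _random_band_outside(loci: Sequence[CytoInterval], rng: np.random.Generator) -> CytoBand:
    for _ in range(1000):
        band = CytoBand(int(rng.integers(1, 121)), "ABCDEF"[rng.integers(0, 6)],
                        int(rng.integers(1, 21)))
        if not any(loc.contains_band(band) for loc in loci):
            return band
    raise RuntimeError("could not sample a band outside the loci")


def gen_gene_annotation_table(loci: Sequence[CytoInterval], n_in: int, n_out: int,
                              fraction_male_reproductive: float = 0.5,
                              seed: int = 0) -> Tuple[pd.DataFrame, Dict]:
    """Annotation table with planted broad-sense candidate flags.

    ``n_in`` genes get band positions inside the loci and ``n_out`` outside;
    each gene independently receives a male-reproductive annotation term
    with the given probability.  The planted candidate flag is true iff the
    gene is inside a locus AND carries a male-reproductive term.
    """
    if not 0.0 <= fraction_male_reproductive <= 1.0:
        raise ValueError("fraction_male_reproductive must be in [0, 1]")
    if (n_in > 0 and not loci) or n_in < 0 or n_out < 0:
        raise ValueError("invalid gene counts or empty loci")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_in + n_out):
        inside = i < n_in
        if inside:
            locus = loci[int(rng.integers(0, len(loci)))]
            band = _random_band_inside(locus, rng)
        else:
            band = _random_band_outside(loci, rng)
        male = bool(rng.random() < fraction_male_reproductive)
        tissue = [str(MALE_REPRODUCTIVE_TERMS[rng.integers(0, len(MALE_REPRODUCTIVE_TERMS))])] \
            if male else [str(_OTHER_TERMS[rng.integers(0, len(_OTHER_TERMS))])]
        function = [str(_OTHER_TERMS[rng.integers(0, len(_OTHER_TERMS))])]
        rows.append({"gene_id": f"G{i + 1:04d}", "band": str(band),
                     "tissue_terms": ";".join(tissue),
                     "function_terms": ";".join(function),
                     "planted_candidate": inside and male})
    table = pd.DataFrame(rows)
    truth = {"candidate_ids": sorted(table.loc[table["planted_candidate"],
                                               "gene_id"].tolist())}
    return table, truth
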