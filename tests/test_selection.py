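"""Codon-model likelihoods, fits and likelihood-ratio tests."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from cspmap import selection as sel
from cspmap import synthetic as syn
from cspmap.codonmodel import (CODON_INDEX, N_CODONS, PhyloTree, SENSE_CODONS,
                               build_rate_matrix, uniform_frequencies)


# ---------------------------------------------------------------------------
# Alignment validation
# ---------------------------------------------------------------------------

def _mk_records(seqs):
    return list(zip(["sim", "sec", "mel"], seqs))


def test_validate_clean_alignment():
    seq = "ATGGCT" * 50
    aln = sel.validate_alignment(_mk_records([seq, seq, seq]))
    assert aln.n_codons == 100
    assert aln.removed_columns == 0


def test_validate_reports_internal_stop_position():
    seqs = ["ATGTAAGCT", "ATGGCAGCT", "ATGGCAGCT"]
    with pytest.raises(sel.AlignmentError, match="codon 2"):
        sel.validate_alignment(_mk_records(seqs))


def test_validate_drops_gap_columns():
    seqs = ["ATG---GCT", "ATGGCAGCT", "ATGGCAGCT"]
    aln = sel.validate_alignment(_mk_records(seqs))
    assert aln.n_codons == 2
    assert aln.removed_columns == 1


def test_validate_strips_shared_terminal_stop():
    seqs = ["ATGGCTTAA", "ATGGCATAA", "ATGGCATGA"]
    aln = sel.validate_alignment(_mk_records(seqs))
    assert aln.n_codons == 2


@pytest.mark.parametrize("seqs, message", [
    (["ATGG", "ATGG", "ATGG"], "divisible"),
    (["ATGGCT", "ATG", "ATGGCT"], "unequal"),
])
def test_validate_rejects_bad_shapes(seqs, message):
    with pytest.raises(sel.AlignmentError, match=message):
        sel.validate_alignment(_mk_records(seqs))


# ---------------------------------------------------------------------------
# Likelihood against a brute-force enumeration oracle
# ---------------------------------------------------------------------------

def loglik_oracle(aln, tree, kappa, omegas, pi):
    """Enumerate the internal node's 61 states with explicitly exponentiated
    per-branch matrices (scipy expm, independent of the eigh route)."""
    pmats = [expm(build_rate_matrix(kappa, w, pi) * t)
             for w, t in zip(omegas, tree.branch_lengths)]
    total = 0.0
    for site in range(aln.n_codons):
        site_l = 0.0
        for x in range(N_CODONS):
            term = pi[x]
            for b in range(3):
                term *= pmats[b][x, aln.codons[b, site]]
            site_l += term
        total += math.log(site_l)
    return total


def test_log_likelihood_matches_enumeration_oracle(rng, trio_tree):
    pi = uniform_frequencies()
    for _ in range(5):
        codons = rng.integers(0, N_CODONS, size=(3, int(rng.integers(2, 6))))
        aln = syn.CodonAlignment(taxa=list(trio_tree.taxa), codons=codons)
        kappa = float(rng.uniform(0.5, 5))
        omegas = rng.uniform(0.05, 3, size=3)
        ll = sel.log_likelihood(aln, trio_tree, kappa, omegas, pi=pi)
        assert ll == pytest.approx(
            loglik_oracle(aln, trio_tree, kappa, omegas, pi), abs=1e-10)


def test_log_likelihood_zero_branches_closed_form():
    pi = uniform_frequencies()
    tree = PhyloTree(taxa=["a", "b", "c"], branch_lengths=np.zeros(3))
    codons = np.tile(np.array([[3, 17, 40]]).T, (1, 1))
    aln = syn.CodonAlignment(taxa=["a", "b", "c"],
                             codons=np.repeat(codons, 1, axis=1))
    aln.codons = np.array([[3], [3], [3]])
    ll = sel.log_likelihood(aln, tree, 2.0, 0.5, pi=pi)
    assert ll == pytest.approx(math.log(pi[3]), abs=1e-12)


def test_log_likelihood_invariant_to_taxon_order(rng, trio_tree):
    """Reversibility: relabelling the star's branches (rerooting the
    unrooted trio) leaves the likelihood unchanged."""
    codons = rng.integers(0, N_CODONS, size=(3, 40))
    aln = syn.CodonAlignment(taxa=["sim", "sec", "mel"], codons=codons)
    pi = uniform_frequencies()
    base = sel.log_likelihood(aln, trio_tree, 2.0, 0.4, pi=pi)
    for perm in ([1, 0, 2], [2, 1, 0], [1, 2, 0]):
        tree = PhyloTree(taxa=[trio_tree.taxa[i] for i in perm],
                         branch_lengths=trio_tree.branch_lengths[perm])
        assert sel.log_likelihood(aln, tree, 2.0, 0.4, pi=pi) == \
            pytest.approx(base, abs=1e-10)


# ---------------------------------------------------------------------------
# LRT arithmetic
# ---------------------------------------------------------------------------

def _fit(model, ll):
    return sel.CodonModelFit(model=model, log_likelihood=ll,
                             branch_lengths=np.ones(3), kappa=2.0, omegas={})


def test_lrt_basics():
    assert sel.lrt(_fit("M0", -100.0), _fit("branch", -95.0), 1).two_delta_ell == 10.0
    equal = sel.lrt(_fit("M0", -50.0), _fit("branch", -50.0), 1)
    assert equal.two_delta_ell == 0.0 and equal.p_value == pytest.approx(1.0)
    assert sel.lrt(_fit("a", -10.0), _fit("b", -10.0 + 3.84 / 2), 1).p_value == \
        pytest.approx(0.05, abs=1e-3)
    # optimizer jitter is clamped
    assert sel.lrt(_fit("a", -10.0), _fit("b", -10.000001), 1).two_delta_ell >= 0.0
    with pytest.raises(ValueError):
        sel.lrt(_fit("a", -1.0), _fit("b", -1.0), 0)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def m0_alignment():
    tree = PhyloTree(taxa=["sim", "sec", "mel"],
                     branch_lengths=np.array([0.2, 0.1, 0.3]),
                     foreground="sim")
    cfg = syn.CodonSimConfig(tree=tree, model="one_ratio",
                             omegas={"omega": 0.3}, kappa=2.0,
                             n_codons=400, seed=21)
    return syn.simulate_codon_alignment(cfg), tree


def test_model_nesting_chain(m0_alignment):
    aln, tree = m0_alignment
    m0 = sel.fit_model(aln, tree, "M0", n_starts=2, seed=0)
    br = sel.fit_model(aln, tree, "branch", n_starts=2, seed=1, warm=m0)
    free = sel.fit_model(aln, tree, "free_ratio", n_starts=2, seed=2, warm=br)
    null = sel.fit_model(aln, tree, "branch_site_null", n_starts=2, seed=3)
    alt = sel.fit_model(aln, tree, "branch_site_A", n_starts=2, seed=4, warm=null)
    tol = 1e-6
    assert m0.log_likelihood <= br.log_likelihood + tol
    assert br.log_likelihood <= free.log_likelihood + tol
    assert null.log_likelihood <= alt.log_likelihood + tol


def test_m0_parameter_recovery(m0_alignment):
    aln, tree = m0_alignment
    fit = sel.fit_model(aln, tree, "M0", n_starts=2, seed=0)
    assert fit.omegas["omega"] == pytest.approx(0.3, rel=0.4)
    assert fit.kappa == pytest.approx(2.0, rel=0.4)
    assert fit.converged


def test_branch_test_detects_planted_acceleration(trio_tree):
    cfg = syn.CodonSimConfig(tree=trio_tree, model="branch",
                             omegas={"omega_fg": 2.0, "omega_bg": 0.2},
                             kappa=2.0, n_codons=500, seed=5)
    aln = syn.simulate_codon_alignment(cfg)
    report = sel.branch_tests(aln, trio_tree, n_starts=2, seed=0)
    assert report.classification == "accelerated"
    assert report.lrt_branch_vs_m0.p_value < 0.01
    assert report.fits["branch"].omegas["omega_fg"] > \
        report.fits["branch"].omegas["omega_bg"]


def test_branch_site_detects_planted_positive_selection(trio_tree):
    cfg = syn.CodonSimConfig(tree=trio_tree, model="branch_site",
                             omegas={"omega0": 0.1, "omega2": 8.0},
                             proportions=(0.5, 0.1), kappa=2.0,
                             n_codons=500, seed=23)
    aln = syn.simulate_codon_alignment(cfg)
    res = sel.branch_site_test(aln, trio_tree, n_starts=2, seed=0)
    assert res.lrt.p_value < 0.05
    assert res.omega2 > 1.0


def test_omega_reported_at_cap(trio_tree):
    """When the foreground signal is saturated the estimate pins at the
    999 bound and is reported as capped."""
    fit = sel.CodonModelFit(model="branch_site_A", log_likelihood=-1.0,
                            branch_lengths=np.ones(3), kappa=2.0,
                            omegas={"omega0": 0.1, "omega2": sel.OMEGA_MAX})
    assert fit.omega_capped
    assert sel.OMEGA_MAX == 999.0
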