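"""Region derivation, coverage and co-required locus inference."""

from itertools import combinations

import numpy as np
import pytest

from cspmap import igmap, synthetic as syn
from cspmap.bands import CytoInterval, parse_band
from conftest import make_line


def test_two_disjoint_intervals_two_regions():
    lines = [make_line("a", "61A", "65F"), make_line("b", "80A", "85F")]
    partition = igmap.derive_regions(lines)
    assert len(partition) == 2


def test_nested_intervals_three_regions():
    lines = [make_line("outer", "61A1", "90A10"), make_line("inner", "70A1", "80A10")]
    partition = igmap.derive_regions(lines)
    assert len(partition) == 3


def test_study_layout_yields_five_regions(study_panel_lines):
    assert len(igmap.derive_regions(study_panel_lines)) == 5


def test_regions_reconstruct_every_interval(study_panel_lines):
    """Round trip: each line's interval is exactly a union of whole regions."""
    partition = igmap.derive_regions(study_panel_lines)
    cov = igmap.coverage_matrix(study_panel_lines, partition)
    for i, ln in enumerate(study_panel_lines):
        covered = [r for j, r in enumerate(partition.regions) if cov[i, j]]
        assert covered, ln.line_id
        assert covered[0].cut_lo == ln._cut_lo()
        assert covered[-1].cut_hi == ln._cut_hi()
        # covered regions are contiguous
        idx = np.nonzero(cov[i])[0]
        assert np.array_equal(idx, np.arange(idx[0], idx[-1] + 1))


def test_coverage_matrix_rows(study_panel_lines):
    partition = igmap.derive_regions(study_panel_lines)
    cov = igmap.coverage_matrix(study_panel_lines, partition)
    rows = {ln.line_id: tuple(cov[i]) for i, ln in enumerate(study_panel_lines)}
    assert rows["L6"] == (True, True, True, True, False)   # regions 1-4
    assert rows["L5"] == (False, True, True, True, False)  # regions 2-4
    assert rows["L3"] == (False, True, True, False, False)
    assert rows["L7"] == (False, False, False, False, True)


def test_partial_region_overlap_is_not_coverage(study_panel_lines):
    partition = igmap.derive_regions(study_panel_lines)
    half = make_line("half", "61A1", "63A1")   # stops inside region 1
    cov = igmap.coverage_matrix(study_panel_lines + [half],
                                igmap.derive_regions(study_panel_lines + [half]))
    # the half line splits region 1; the original region-1 line covers both
    assert cov[-1].sum() == 1


def test_infer_corequired_study_pattern(study_panel_lines):
    """Lines covering regions 2-4 break down; pairs 2-3 / 3-4 do not, so the
    minimal co-required set {2,4} wins over {2,3,4} by set size."""
    partition = igmap.derive_regions(study_panel_lines)
    cov = igmap.coverage_matrix(study_panel_lines, partition)
    flags = [ln.breakdown_flag for ln in study_panel_lines]
    hyps = igmap.infer_corequired(cov, flags, max_set_size=3)
    top = hyps[0]
    assert top.required_regions == frozenset({2, 4})
    assert top.n_consistent == len(study_panel_lines)
    assert top.exceptions == []
    # {2,3,4} ties on score but loses on minimality
    triple = next(h for h in hyps if h.required_regions == frozenset({2, 3, 4}))
    assert triple.n_consistent == top.n_consistent


def test_single_locus_truth_recovered():
    panel_cfg = syn.PanelSimConfig(corequired_set={1}, n_lines=30, seed=3)
    panel, truth = syn.gen_introgression_panel(panel_cfg)
    lines = [make_line(r.line_id, r.start_band, r.end_band, bool(r.true_breakdown))
             for r in panel.itertuples()]
    partition = igmap.derive_regions(lines)
    cov = igmap.coverage_matrix(lines, partition)
    hyps = igmap.infer_corequired(cov, [ln.breakdown_flag for ln in lines],
                                  max_set_size=3)
    assert hyps[0].required_regions == frozenset({1})
    assert hyps[0].exceptions == []


def test_all_lines_break_down_degenerate():
    cov = np.array([[True, False], [True, True], [False, True]])
    hyps = igmap.infer_corequired(cov, [True, True, True], max_set_size=2)
    assert hyps[0].required_regions   # non-empty by construction
    assert hyps[0].n_consistent == 2


def test_no_breakdown_lines_rejected():
    cov = np.ones((3, 2), bool)
    with pytest.raises(ValueError):
        igmap.infer_corequired(cov, [False] * 3)


def test_predict_phenotype():
    hyp = igmap.LocusHypothesis(required_regions=frozenset({2, 4}), n_consistent=0)
    assert igmap.predict_phenotype(hyp, np.array([0, 1, 1, 1, 0], bool))
    assert not igmap.predict_phenotype(hyp, np.array([0, 0, 1, 1, 0], bool))
    empty = igmap.LocusHypothesis(required_regions=frozenset(), n_consistent=0)
    with pytest.raises(ValueError):
        igmap.predict_phenotype(empty, np.ones(5, bool))


def brute_force_best(coverage, flags, max_set_size):
    """Independent exhaustive oracle over all region subsets."""
    k = coverage.shape[1]
    best = None
    for size in range(1, max_set_size + 1):
        for subset in combinations(range(k), size):
            predicted = coverage[:, subset].all(axis=1)
            score = int((predicted == flags).sum())
            key = (-score, size, subset)
            if best is None or key < best[0]:
                best = (key, frozenset(s + 1 for s in subset), score)
    return best[1], best[2]


def test_infer_agrees_with_brute_force(rng):
    for _ in range(25):
        k = int(rng.integers(2, 8))
        n = int(rng.integers(5, 25))
        coverage = rng.random((n, k)) < 0.5
        flags = rng.random(n) < 0.5
        if not flags.any():
            flags[0] = True
        hyps = igmap.infer_corequired(coverage, flags, max_set_size=k)
        expected_set, expected_score = brute_force_best(coverage, flags, k)
        assert hyps[0].n_consistent == expected_score
        assert hyps[0].required_regions == expected_set


def test_adding_consistent_line_never_lowers_top_score(rng):
    coverage = rng.random((20, 5)) < 0.5
    flags = list(rng.random(20) < 0.4)
    if not any(flags):
        flags[0] = True
    top = igmap.infer_corequired(coverage, flags, max_set_size=3)[0]
    req_idx = [r - 1 for r in top.required_regions]
    new_row = np.zeros(5, bool)
    new_row[req_idx] = True
    grown = np.vstack([coverage, new_row])
    top2 = igmap.infer_corequired(grown, flags + [True], max_set_size=3)[0]
    assert top2.n_consistent >= top.n_consistent


def test_suppressor_reported_in_exceptions():
    cfg = syn.PanelSimConfig(n_lines=60, suppressor_lines=1, seed=9)
    panel, truth = syn.gen_introgression_panel(cfg)
    lines = [make_line(r.line_id, r.start_band, r.end_band, bool(r.true_breakdown))
             for r in panel.itertuples()]
    partition = igmap.derive_regions(lines)
    cov = igmap.coverage_matrix(lines, partition)
    hyps = igmap.infer_corequired(cov, [ln.breakdown_flag for ln in lines],
                                  line_ids=[ln.line_id for ln in lines],
                                  max_set_size=3)
    top = hyps[0]
    assert top.required_regions == frozenset(truth["corequired_set"])
    assert (truth["suppressor_ids"][0], "suppressor") in top.exceptions
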