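import numpy as np
import pandas as pd
import pytest

from cspmap.bands import CytoInterval, parse_band
from cspmap.codonmodel import PhyloTree
from cspmap.igmap import IntrogressionLine


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio_tree():
    return PhyloTree(taxa=["sim", "sec", "mel"],
                     branch_lengths=np.array([0.2, 0.1, 0.3]),
                     foreground="sim")


def make_line(line_id, start, end, flag=None):
    return IntrogressionLine(line_id=line_id,
                             interval=CytoInterval(parse_band(start),
                                                   parse_band(end)),
                             breakdown_flag=flag)


@pytest.fixture
def study_panel_lines():
    """A miniature panel echoing the study layout on a 5-region tiling:
    single flanking regions, adjacent pairs, the 2-3-4 triple and a
    four-region span.  Only lines covering both region 2 and region 4
    break down."""
    spans = {
        "L1": ("61A1", "65A10", False),    # region 1 only
        "L2": ("65A11", "70A10", False),   # region 2 only
        "L3": ("65A11", "75A10", False),   # regions 2-3
        "L4": ("70A11", "80A10", False),   # regions 3-4
        "L5": ("65A11", "80A10", True),    # regions 2-4 (covers both loci)
        "L6": ("61A1", "80A10", True),     # regions 1-4
        "L7": ("85A1", "90A10", False),    # region 5 only
    }
    return [make_line(k, s, e, f) for k, (s, e, f) in spans.items()]


@pytest.fixture
def trial_frame():
    """Small hand-written mating-trial table covering the edge cases."""
    return pd.DataFrame([
        # female, line, block, vial1, wt, ebony
        ("F1", "A", 1, 12, 30, 10),    # clean: P2 = 0.75
        ("F2", "A", 1, 0, 20, 20),     # failed first mating
        ("F3", "A", 2, 9, 0, 0),       # failed second mating
        ("F4", "B", 1, 15, 0, 25),     # P2 = 0
        ("F5", "B", 2, 7, 10, 9),      # fecundity 19: restricted drops
        ("F6", "B", 2, 7, 25, 15),     # fecundity 40
    ], columns=["female_id", "line_id", "block",
                "vial1_ebony", "vial23_wildtype", "vial23_ebony"])
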