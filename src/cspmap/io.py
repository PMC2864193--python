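"""File readers and writers for the pipeline's plain-text formats.

Tabular inputs are TSV (tab-separated, UTF-8, header row); sequence inputs
are FASTA and newick (via Biopython); reports are JSON.  Readers validate
eagerly and report row-level problems with line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bands import parse_band
from .codonmodel import PhyloTree
from .expression import CT_COLUMNS
from .paternity import TRIAL_COLUMNS

__all__ = [
    "read_trials", "read_intervals", "read_ct", "read_annotations",
    "read_flags", "read_fasta", "read_newick",
    "write_tsv", "write_json", "write_fasta", "write_newick",
]

PathLike = Union[str, Path]


class TableError(ValueError):
    """A TSV failed validation; the message lists row-level problems."""


def _read_tsv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing columns {missing}")
    return df


def _coerce_counts(df: pd.DataFrame, cols: Sequence[str], path: PathLike) -> pd.DataFrame:
    errors: List[str] = []
    for col in cols:
        values = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[values.isna() | (values < 0) | (values % 1 != 0)]:
            errors.append(f"line {i + 2}: column {col!r} has invalid count "
                          f"{df.loc[i, col]!r}")
        df[col] = values
    if errors:
        raise TableError(f"{path}: " + "; ".join(errors[:20]))
    return df.astype({c: int for c in cols})


def read_trials(path: PathLike) -> pd.DataFrame:
    """Mating-trial TSV -> validated DataFrame (counts as non-negative ints)."""
    df = _read_tsv(path, TRIAL_COLUMNS)
    return _coerce_counts(df, ["vial1_ebony", "vial23_wildtype", "vial23_ebony"], path)


def read_intervals(path: PathLike) -> pd.DataFrame:
    """Introgression-interval TSV (line_id, start_band, end_band[, flags])."""
    df = _read_tsv(path, ("line_id", "start_band", "end_band"))
    errors = []
    for i, row in df.iterrows():
        try:
            parse_band(row["start_band"])
            parse_band(row["end_band"])
        except ValueError as exc:
            errors.append(f"line {i + 2}: {exc}")
    if errors:
        raise TableError(f"{path}: " + "; ".join(errors[:20]))
    if "true_breakdown" in df.columns:
        df["true_breakdown"] = df["true_breakdown"].map(
            {"True": True, "False": False, "1": True, "0": False})
    return df


def read_flags(path: PathLike) -> pd.DataFrame:
    """Per-line breakdown flag TSV (line_id, breakdown_flag)."""
    df = _read_tsv(path, ("line_id", "breakdown_flag"))
    df["breakdown_flag"] = df["breakdown_flag"].map(
        {"True": True, "False": False, "1": True, "0": False})
    if df["breakdown_flag"].isna().any():
        raise TableError(f"{path}: non-boolean breakdown_flag values")
    return df


def read_ct(path: PathLike) -> pd.DataFrame:
    """qPCR Ct TSV -> DataFrame with finite positive Ct values."""
    df = _read_tsv(path, CT_COLUMNS)
    errors = []
    for col in ("ct_target", "ct_reference"):
        values = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[values.isna() | (values <= 0)]:
            errors.append(f"line {i + 2}: column {col!r} has invalid Ct "
                          f"{df.loc[i, col]!r}")
        df[col] = values
    if errors:
        raise TableError(f"{path}: " + "; ".join(errors[:20]))
    df["replicate"] = pd.to_numeric(df["replicate"]).astype(int)
    return df


def read_annotations(path: PathLike) -> pd.DataFrame:
    """Gene annotation TSV (gene_id, band, tissue_terms, function_terms)."""
    df = _read_tsv(path, ("gene_id", "band"))
    errors = []
    for i, row in df.iterrows():
        try:
            parse_band(row["band"])
        except ValueError as exc:
            errors.append(f"line {i + 2}: {exc}")
    if errors:
        raise TableError(f"{path}: " + "; ".join(errors[:20]))
    for col in ("tissue_terms", "function_terms"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("")
    return df


def read_fasta(path: PathLike) -> List[Tuple[str, str]]:
    """FASTA -> list of (name, sequence), preserved verbatim."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_newick(path: PathLike, foreground: Optional[str] = None) -> PhyloTree:
    """3-leaf newick -> :class:`PhyloTree` (errors on any other leaf count)."""
    tree = Phylo.read(str(path), "newick")
    leaves = tree.get_terminals()
    if len(leaves) != 3:
        raise ValueError(f"{path}: tree must have exactly 3 leaves, "
                         f"got {len(leaves)}")
    names = [leaf.name for leaf in leaves]
    if len(set(names)) != 3:
        raise ValueError(f"{path}: duplicate leaf names")
    lengths = np.array([leaf.branch_length if leaf.branch_length is not None else 0.0
                        for leaf in leaves], float)
    return PhyloTree(taxa=names, branch_lengths=lengths, foreground=foreground)


def write_tsv(df: pd.DataFrame, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_fasta(records: Sequence[Tuple[str, str]], path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_newick(tree: PhyloTree, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")
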