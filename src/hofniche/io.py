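"""Readers and writers for the pipeline's plain-text formats.

Tables travel as TSV with a header row and the site/OTU/species identifier in
the first column; missing cells use the token ``NA``.  Sequences are FASTA,
trees Newick.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "read_table",
    "write_table",
    "read_fasta",
    "write_fasta",
    "read_tree",
    "write_tree",
    "config_hash",
]

NA_TOKEN = "NA"

_KINDS = ("environment", "abundance", "optima", "traits", "matrix")


def read_table(path, kind: str = "matrix") -> pd.DataFrame:
    """Read a TSV table and validate it for its role in the pipeline.

    Kinds
    -----
    - ``environment``: site x variable, numeric, NA allowed.
    - ``abundance``: OTU x site, numeric, non-negative, NA forbidden.
    - ``optima``: long format with columns otu/variable/model/optimum/...
    - ``traits``: species x trait, numeric, NA allowed.
    - ``matrix``: generic numeric table (e.g., a dissimilarity matrix).

    Raises
    ------
    ValueError
        On duplicate identifiers (named in the message) or non-numeric cells
        outside the ``NA`` token.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=None, dtype=str,
                     keep_default_na=False)
    if kind == "optima":
        out = df.replace(NA_TOKEN, np.nan).replace("", np.nan)
        for col in ("optimum", "lo", "hi", "support"):
            if col in out.columns:
                out[col] = pd.to_numeric(out[col])
        return out
    idcol = df.columns[0]
    ids = df[idcol]
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate identifier(s) in {path}: {dup[:5]}")
    df = df.set_index(idcol)
    for col in df.columns:
        bad = df[col][~df[col].isin([NA_TOKEN, ""]) &
                      pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric cell(s) in column {col!r} of {path}: "
                f"{bad.iloc[0]!r} at row {bad.index[0]!r}")
    out = df.replace({NA_TOKEN: np.nan, "": np.nan}).astype(float)
    if kind == "abundance":
        if out.isna().any().any():
            raise ValueError("abundance tables cannot contain missing values")
        if (out < 0).any().any():
            raise ValueError("abundance counts must be non-negative")
    return out


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a table as TSV with ``NA`` for missing cells."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=index)


def read_fasta(path) -> dict[str, str]:
    """FASTA file to an ordered id -> sequence mapping (duplicate ids error)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance logs."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
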