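"""Fractionated assignment of amplicon reads to reference OTUs.

Each read is aligned against every candidate full-length reference sequence
(semi-global: the read must align end-to-end, the reference region is free)
and assigned to all OTUs whose best alignment reaches the identity cutoff —
by default 99%, the approximate error ceiling of short-read sequencing.
Identity is matches / aligned columns, gap columns included.  A read matching
k OTUs contributes 1/k of a count to each (fractionated counting), so read
mass is conserved: the fractional counts of one site sum to the number of
matched reads.

A k-mer prescreen shortlists references sharing at least one exact word with
the read; at 99% identity a >= 50 bp read is guaranteed to share words of the
default size, so the prescreen cannot lose true matches at the default cutoff.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "make_aligner",
    "read_identity",
    "match_read",
    "fractionate_counts",
    "prevalence_filter",
    "assign_reads",
]

_PRESCREEN_K = 12


def make_aligner() -> Align.PairwiseAligner:
    """Aligner with match +1, mismatch -1, gap -2 and free reference end gaps
    (the read aligns globally, anywhere within the reference)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # free end gaps flanking the read (gap columns in the query row): the
    # read aligns globally, its position within the reference is free
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


def read_identity(read: str, reference: str,
                  aligner: Optional[Align.PairwiseAligner] = None) -> float:
    """Identity fraction of the best alignment of ``read`` within ``reference``.

    Identity = matching columns / aligned columns, counting internal gap
    columns in the denominator but not the free reference flanks.
    """
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(reference.upper(), read.upper())[0]
    tgt_blocks, qry_blocks = aln.aligned
    if len(tgt_blocks) == 0:
        return 0.0
    target, query = aln.target, aln.query
    matches = 0
    aligned_cols = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(tgt_blocks, qry_blocks):
        if prev_t is not None:
            aligned_cols += (ts - prev_t) + (qs - prev_q)  # internal gap columns
        seg_t = target[ts:te]
        seg_q = query[qs:qe]
        matches += sum(1 for a, b in zip(seg_t, seg_q) if a == b)
        aligned_cols += te - ts
        prev_t, prev_q = te, qe
    # unaligned read overhangs (read bases in end gaps) count as columns too
    q_first, q_last = qry_blocks[0][0], qry_blocks[-1][1]
    aligned_cols += q_first + (len(query) - q_last)
    return matches / aligned_cols if aligned_cols else 0.0


def _kmer_index(refs: dict[str, str], k: int) -> dict[str, set]:
    index: dict[str, set] = defaultdict(set)
    for otu, seq in refs.items():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            index[s[i:i + k]].add(otu)
    return index


def match_read(read: str, refs: dict[str, str], cutoff: float = 0.99,
               aligner: Optional[Align.PairwiseAligner] = None,
               kmer_index: Optional[dict] = None,
               prescreen: bool = True) -> set[str]:
    """OTU ids whose reference matches the read at >= ``cutoff`` identity.

    The cutoff is inclusive: a 100-bp read with exactly one mismatch
    (identity 0.99) matches at the default cutoff.
    """
    if not refs:
        raise ValueError("empty reference set")
    if len(read) < 50:
        raise ValueError("read shorter than 50 bp")
    if aligner is None:
        aligner = make_aligner()
    candidates: Iterable[str] = refs
    if prescreen:
        if kmer_index is None:
            kmer_index = _kmer_index(refs, _PRESCREEN_K)
        r = read.upper()
        cand: set[str] = set()
        for i in range(0, len(r) - _PRESCREEN_K + 1):
            cand |= kmer_index.get(r[i:i + _PRESCREEN_K], set())
        candidates = cand
    return {otu for otu in candidates
            if read_identity(read, refs[otu], aligner) >= cutoff}


def fractionate_counts(match_sets: Sequence[set[str]], site_labels: Sequence[str],
                       otu_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Fractionated OTU x site count table from per-read match sets.

    A read matching k OTUs contributes 1/k to each of them in its site;
    unmatched reads (empty sets) contribute nothing.
    """
    if len(match_sets) != len(site_labels):
        raise ValueError("one site label per read required")
    totals: dict[tuple[str, str], float] = defaultdict(float)
    seen = set()
    for matches, site in zip(match_sets, site_labels):
        seen.add(site)
        if not matches:
            continue
        share = 1.0 / len(matches)
        for otu in matches:
            totals[(otu, site)] += share
    if otu_ids is None:
        otu_ids = sorted({otu for otu, _ in totals})
    sites = sorted(seen)
    table = pd.DataFrame(0.0, index=pd.Index(otu_ids, name="otu"), columns=sites)
    for (otu, site), val in totals.items():
        table.loc[otu, site] = val
    return table


def prevalence_filter(table: pd.DataFrame, min_sites: int = 25) -> pd.DataFrame:
    """Retain OTUs detected (fractional count > 0) in >= ``min_sites`` sites."""
    if min_sites > table.shape[1]:
        raise ValueError("min_sites exceeds the number of sites")
    return table.loc[(table > 0).sum(axis=1) >= min_sites]


def assign_reads(reads: Sequence[tuple[str, str, str]], refs: dict[str, str],
                 cutoff: float = 0.99, prescreen: bool = True) -> pd.DataFrame:
    """Assign ``(read_id, site, sequence)`` records to reference OTUs.

    Returns the fractionated OTU x site table over all reference OTUs
    (rows of unmatched OTUs kept as zeros).
    """
    aligner = make_aligner()
    index = _kmer_index(refs, _PRESCREEN_K) if prescreen else None
    match_sets, sites = [], []
    for _, site, seq in reads:
        match_sets.append(match_read(seq, refs, cutoff=cutoff, aligner=aligner,
                                     kmer_index=index, prescreen=prescreen))
        sites.append(site)
    return fractionate_counts(match_sets, sites, otu_ids=sorted(refs))
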