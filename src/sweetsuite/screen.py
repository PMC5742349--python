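"""Screening of putative SWEET/SemiSWEET records.

Four filters are applied in a fixed order: 100%-identity deduplication,
fragment removal, PQ-loop motif detection, and a minimum transmembrane-helix
(TMH) count. TMHs are predicted with a transparent sliding-window
Kyte-Doolittle hydropathy rule rather than an HMM: a position is a helix
candidate when the mean hydropathy of the window centred on it reaches a
threshold, candidate runs separated by small gaps are merged, and runs at
least ``min_helix_len`` long are reported as helices. This is a deliberately
simple, reproducible stand-in for HMM-based topology predictors; it is tuned
for clearly amphipathic sequences (long hydrophobic blocks between polar
loops) and is not a general-purpose topology tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as _KD

from .records import ProteinRecord, check_unique_accessions, validate_sequence

#: Kyte-Doolittle hydropathy values; X (unknown residue) is scored neutral.
KYTE_DOOLITTLE = dict(_KD, X=0.0)

# Hydropathy classes used by the synthetic generator's substitution model.
HYDROPHOBIC_RESIDUES = "LIVFAM"
LOOP_RESIDUES = "KREDNQSTGP"


@dataclass(frozen=True)
class TMHTopology:
    """Predicted transmembrane helices as sorted 1-based inclusive intervals."""

    helices: tuple[tuple[int, int], ...]

    @property
    def count(self) -> int:
        return len(self.helices)


def predict_tmh(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    min_helix_len: int = 15,
    merge_gap: int = 3,
) -> TMHTopology:
    """Predict TMHs by centred sliding-window Kyte-Doolittle hydropathy.

    A position (with a full window around it) is a helix candidate iff the
    window mean hydropathy is >= ``threshold``. Maximal candidate runs whose
    separating gap is shorter than ``merge_gap`` are merged; merged runs of
    length >= ``min_helix_len`` become helices.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if min_helix_len < 1 or merge_gap < 0:
        raise ValueError("min_helix_len must be >= 1 and merge_gap >= 0")
    seq = validate_sequence(sequence)
    n = len(seq)
    if n < window:
        return TMHTopology(helices=())
    values = np.array([KYTE_DOOLITTLE[c] for c in seq])
    # means[i] = mean over seq[i : i + window]; centre position = i + window//2
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    half = window // 2
    candidate = np.zeros(n, dtype=bool)
    candidate[half : n - half] = means >= threshold
    runs = _runs(candidate)
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    helices = tuple(
        (s + 1, e + 1) for s, e in merged if e - s + 1 >= min_helix_len
    )
    return TMHTopology(helices=helices)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 0-based inclusive (start, end)."""
    out: list[tuple[int, int]] = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        out.append((int(idx[s]), int(idx[e])))
    return out


def find_pq_motif(
    record: ProteinRecord,
    topology: TMHTopology,
    mode: str = "strict_PQ",
    flank: int = 10,
) -> Optional[int]:
    """Locate the PQ-loop signature near the first predicted helix.

    In ``strict_PQ`` mode the first 1-based position ``i`` with
    ``sequence[i] == 'P'`` and ``sequence[i+1] == 'Q'`` inside the first helix
    extended by ``flank`` residues on both sides is returned; ``relaxed_P``
    only requires the proline (the glutamine of the dipeptide is conserved in
    SemiSWEETs but not throughout the family). Returns ``None`` when there is
    no helix or no hit.
    """
    if mode not in ("strict_PQ", "relaxed_P"):
        raise ValueError(f"unknown motif mode {mode!r}")
    if not topology.helices:
        return None
    seq = record.sequence
    start, end = topology.helices[0]
    lo = max(1, start - flank)
    hi = min(len(seq), end + flank)
    for i in range(lo, hi + 1):
        if seq[i - 1] != "P":
            continue
        if mode == "relaxed_P":
            return i
        if i < len(seq) and seq[i] == "Q":
            return i
    return None


def dedupe(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], list[tuple[str, str]]]:
    """Remove byte-identical sequences, keeping the lexicographically
    smallest accession as representative.

    Returns the kept records (input order preserved) and ``(removed,
    representative)`` accession pairs.
    """
    check_unique_accessions(records)
    by_seq: dict[str, str] = {}
    for rec in records:
        best = by_seq.get(rec.sequence)
        if best is None or rec.accession < best:
            by_seq[rec.sequence] = rec.accession
    kept = [r for r in records if by_seq[r.sequence] == r.accession]
    removed = [
        (r.accession, by_seq[r.sequence])
        for r in records
        if by_seq[r.sequence] != r.accession
    ]
    return kept, removed


@dataclass
class ScreenReport:
    """Outcome of the screening stage.

    ``frame`` holds one row per input record: accession, passed, tmh_count,
    pq_hit (1-based or <NA>), removal_reason in {duplicate, fragment,
    no_motif, too_few_tmh, none}. ``kept`` are the passing records in input
    order.
    """

    frame: pd.DataFrame
    kept: list[ProteinRecord] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return self.frame["removal_reason"].value_counts().to_dict()

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def apply_filters(
    records: Sequence[ProteinRecord],
    min_tmh: int = 3,
    fragment_max_fraction: float = 0.5,
    motif_mode: str = "strict_PQ",
    motif_flank: int = 10,
    window: int = 19,
    threshold: float = 1.6,
    min_helix_len: int = 15,
    merge_gap: int = 3,
) -> ScreenReport:
    """Run the screening filters in the fixed order
    dedupe -> fragment -> motif -> TMH count.

    A record is a fragment when its length is below ``fragment_max_fraction``
    times the median length of the post-dedupe set. Each removed record gets
    exactly one removal reason: the first failing filter.
    """
    if not records:
        raise ValueError("apply_filters requires a non-empty record list")
    kept_dedupe, removed_pairs = dedupe(records)
    dup_reason = {acc: rep for acc, rep in removed_pairs}
    median_len = float(np.median([len(r) for r in kept_dedupe]))
    frag_cutoff = fragment_max_fraction * median_len

    rows = []
    kept: list[ProteinRecord] = []
    for rec in records:
        topo = predict_tmh(rec.sequence, window, threshold, min_helix_len, merge_gap)
        pq = find_pq_motif(rec, topo, mode=motif_mode, flank=motif_flank)
        if rec.accession in dup_reason:
            reason = "duplicate"
        elif len(rec) < frag_cutoff:
            reason = "fragment"
        elif pq is None:
            reason = "no_motif"
        elif topo.count < min_tmh:
            reason = "too_few_tmh"
        else:
            reason = "none"
            kept.append(rec)
        rows.append(
            {
                "accession": rec.accession,
                "passed": reason == "none",
                "tmh_count": topo.count,
                "pq_hit": pq,
                "removal_reason": reason,
            }
        )
    frame = pd.DataFrame(rows).astype({"pq_hit": "Int64"})
    return ScreenReport(frame=frame, kept=kept)
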