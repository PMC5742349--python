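"""Repeat-unit architecture of SWEET-family transporters.

The family is built from a 3-TMH repeat unit. Classification by helix count:
SemiSWEETs carry one unit (3-4 TMHs), SWEETs two units joined by a single
linker helix (6-7 TMHs), extraSWEETs roughly double that (14-15), and
superSWEETs (>= 18) stack further duplications. Proteins outside every bin
are "atypical". Decomposition assigns helices to triplet units and
single-helix linkers; fusion evidence aligns each unit's residue span against
reference sequences and flags units whose best percent identity reaches a
threshold (default 70).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .records import ProteinRecord
from .screen import TMHTopology
from . import ssn

#: Default class bins: exact counts, except superSWEET which is open-ended.
DEFAULT_BINS: dict[str, tuple[int, ...]] = {
    "semiSWEET": (3, 4),
    "SWEET": (6, 7),
    "extraSWEET": (14, 15),
}
SUPER_MIN_TMH = 18

ARCH_CLASSES = ("semiSWEET", "SWEET", "extraSWEET", "superSWEET", "atypical")


def classify(
    topology: TMHTopology | int,
    bins: dict[str, tuple[int, ...]] | None = None,
    super_min: int = SUPER_MIN_TMH,
) -> str:
    """Map a TMH count to an architecture class. Pure function of the count."""
    count = topology if isinstance(topology, int) else topology.count
    if count < 0:
        raise ValueError("tmh_count must be >= 0")
    bins = DEFAULT_BINS if bins is None else bins
    seen: set[int] = set()
    for name, counts in bins.items():
        if seen & set(counts):
            raise ValueError("overlapping bins in configuration")
        seen |= set(counts)
    for name, counts in bins.items():
        if count in counts:
            return name
    if count >= super_min:
        return "superSWEET"
    return "atypical"


@dataclass(frozen=True)
class UnitSpan:
    """One architectural element.

    ``unit_type`` is ``triplet`` (3 helices), ``linker`` (1 helix) or
    ``unresolved`` (trailing helices with no plan). ``tmh_indices`` are
    1-based helix ordinals; ``seq_span`` is the 1-based inclusive residue
    interval, cut at the midpoints of the flanking loops so each unit carries
    its loop context.
    """

    unit_type: str
    tmh_indices: tuple[int, ...]
    seq_span: tuple[int, int]


@dataclass(frozen=True)
class ArchitectureCall:
    accession: str
    tmh_count: int
    arch_class: str
    units: tuple[UnitSpan, ...]


@dataclass(frozen=True)
class FusionEvidence:
    unit_index: int
    best_reference_accession: str
    percent_identity: float
    evalue: float
    flagged: bool


def _greedy_plan(count: int) -> list[tuple[str, tuple[int, ...]]]:
    """Greedy left-to-right decomposition into triplets with single-helix
    linkers between them; 1-2 trailing helices become ``unresolved``."""
    plan: list[tuple[str, tuple[int, ...]]] = []
    i = 1
    while count - i + 1 >= 3:
        plan.append(("triplet", (i, i + 1, i + 2)))
        i += 3
        # a linker is only taken when at least one more triplet follows it
        if count - i + 1 >= 4:
            plan.append(("linker", (i,)))
            i += 1
    if i == count:
        # one trailing helix: the canonical 4-TMH plan's linker
        plan.append(("linker", (i,)))
    elif i < count:
        plan.append(("unresolved", tuple(range(i, count + 1))))
    return plan


def decompose_units(topology: TMHTopology, sequence: str) -> list[UnitSpan]:
    """Decompose a topology into repeat units and linker helices.

    Canonical plans fall out of the greedy rule: 3 -> [triplet];
    4 -> [triplet, linker]; 7 -> [triplet, linker, triplet];
    15 -> 4 triplets alternating with 3 linkers. Residue spans are cut at the
    midpoints of the loops between consecutive helices; the first span starts
    at residue 1 and the last ends at the sequence end.
    """
    if topology.count == 0:
        raise ValueError("cannot decompose a topology with zero helices")
    helices = topology.helices
    n = len(sequence)
    # boundary[i] = first residue of the element starting at helix i+1
    cuts = [1]
    for (s1, e1), (s2, _e2) in zip(helices, helices[1:]):
        cuts.append((e1 + s2) // 2 + 1)  # midpoint of the loop between them
    cuts.append(n + 1)

    spans: list[UnitSpan] = []
    for unit_type, idx in _greedy_plan(topology.count):
        start = cuts[idx[0] - 1]
        end = cuts[idx[-1]] - 1
        spans.append(UnitSpan(unit_type=unit_type, tmh_indices=idx, seq_span=(start, end)))
    return spans


def call_architecture(
    accession: str,
    topology: TMHTopology,
    sequence: str,
    bins: dict[str, tuple[int, ...]] | None = None,
) -> ArchitectureCall:
    arch_class = classify(topology, bins=bins)
    units = tuple(decompose_units(topology, sequence)) if topology.count else ()
    return ArchitectureCall(
        accession=accession,
        tmh_count=topology.count,
        arch_class=arch_class,
        units=units,
    )


def detect_fusion(
    call: ArchitectureCall,
    sequence: str,
    references: Sequence[ProteinRecord],
    params: Optional["ssn.SimilarityParams"] = None,
    fusion_identity_threshold: float = 70.0,
) -> list[FusionEvidence]:
    """Align each triplet unit against every reference; report the best hit.

    A unit whose best percent identity is >= ``fusion_identity_threshold``
    is flagged as duplication/fusion evidence. Zero-score (empty) alignments
    count as 0% identity and are never flagged.
    """
    if not references:
        raise ValueError("detect_fusion requires a non-empty reference set")
    params = params or ssn.SimilarityParams()
    out: list[FusionEvidence] = []
    for i, unit in enumerate(call.units):
        if unit.unit_type != "triplet":
            continue
        s, e = unit.seq_span
        sub = ProteinRecord(accession=f"{call.accession}/unit{i}", sequence=sequence[s - 1 : e])
        best = None
        for ref in references:
            edge = ssn.pairwise_similarity(sub, ref, params)
            if best is None or edge.bitscore > best[0].bitscore:
                best = (edge, ref.accession)
        edge, ref_acc = best
        out.append(
            FusionEvidence(
                unit_index=i,
                best_reference_accession=ref_acc,
                percent_identity=edge.percent_identity,
                evalue=edge.evalue,
                flagged=edge.percent_identity >= fusion_identity_threshold,
            )
        )
    return out
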