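"""Synthetic SWEET-like protein families with planted truth.

The generator emulates the statistical structure the analysis pipeline
assumes: families are built by concatenating 3-TMH repeat units (three
hydrophobic blocks separated by hydrophilic loops, with a PQ dipeptide in
the loop flanking the first block) and single-helix linkers, then diverged
by per-site substitutions that stay within the hydropathy class of the
ancestral residue. Selected ancestral columns are invariant (never mutated),
selected column pairs covary (they only ever hold state combinations from an
explicit table), and fragments and byte-identical duplicates are injected.
Every planted feature is reported in a truth table so downstream stages can
be scored against known answers.

Coordinates in the truth tables are 1-based positions in the ungapped
ancestral sequence of each family; full-length family members share this
coordinate system because divergence introduces no indels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import architecture
from .records import ProteinRecord, TAXON_GROUPS
from .screen import HYDROPHOBIC_RESIDUES, LOOP_RESIDUES

#: Default geometry: hydrophobic block and loop lengths (residues). The block
#: length is chosen so the screening stage's hydropathy predictor (window 19,
#: threshold 1.6, min helix length 15) detects each block as one helix with
#: margin to spare under within-class substitution noise.
DEFAULT_BLOCK_LEN = 28
DEFAULT_LOOP_LEN = 12

PlanElement = tuple[str, Optional[str]]  # ("unit", unit_id) or ("linker", None)


@dataclass(frozen=True)
class UnitTemplate:
    """Ancestral 3-TMH repeat unit.

    ``sequence`` is loop-block-loop-block-loop-block-loop; ``pq_position`` is
    the 1-based index of the planted 'P' of the PQ dipeptide, inside the loop
    preceding the first block.
    """

    unit_id: str
    sequence: str
    pq_position: int

    def __post_init__(self) -> None:
        p = self.pq_position
        if not (1 <= p < len(self.sequence)):
            raise ValueError("pq_position out of range")
        if self.sequence[p - 1 : p + 1] != "PQ":
            raise ValueError("pq_position does not point at a PQ dipeptide")


@dataclass(frozen=True)
class CovaryingPair:
    """Compensatory column pair: only combinations in ``states`` occur."""

    pos_a: int
    pos_b: int
    states: tuple[tuple[str, str], ...] = (("E", "K"), ("K", "E"))


@dataclass(frozen=True)
class EvolutionScenario:
    """Parameters of one simulated radiation.

    ``architecture_per_family`` gives, per family, either a target TMH count
    (3, 4, 7, 15, 25 or any other count, expanded by the greedy unit/linker
    rule) or an explicit plan as a sequence of ("unit", unit_id) /
    ("linker", None) elements. ``substitution_rate`` is the per-site
    probability that a lineage resamples the residue within its hydropathy
    class. ``invariant_columns`` and ``covarying_pairs`` use 1-based
    ancestral coordinates and apply to every family (they must fit the
    shortest ancestor).
    """

    n_families: int = 2
    seqs_per_family: int = 20
    architecture_per_family: tuple = (7, 7)
    substitution_rate: float = 0.1
    invariant_columns: frozenset[int] = frozenset()
    covarying_pairs: tuple[CovaryingPair, ...] = ()
    fragment_rate: float = 0.0
    duplicate_rate: float = 0.0
    seed: int = 0
    block_len: int = DEFAULT_BLOCK_LEN
    loop_len: int = DEFAULT_LOOP_LEN
    #: Residue written at planted invariant columns (None keeps the ancestral
    #: residue). The default tryptophan is distinctive: it belongs to neither
    #: mutable hydropathy class, mirroring the real family whose single most
    #: conserved position is an aromatic, and makes planted truth identifiable.
    invariant_residue: Optional[str] = "W"

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "fragment_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_families < 1 or self.seqs_per_family < 1:
            raise ValueError("n_families and seqs_per_family must be >= 1")
        if len(self.architecture_per_family) != self.n_families:
            raise ValueError(
                "architecture_per_family must list one plan per family"
            )


@dataclass
class TruthTable:
    """Planted truth: one row per emitted sequence and one per family."""

    sequences: pd.DataFrame
    families: pd.DataFrame
    ancestors: dict[str, str] = field(default_factory=dict)

    def write(self, seq_path, family_path) -> None:
        self.sequences.to_csv(seq_path, sep="\t", index=False)
        self.families.to_csv(family_path, sep="\t", index=False)


def _hydrophobic_blocks(seq: str, min_len: int = 10) -> list[tuple[int, int]]:
    """Maximal runs of hydrophobic-class residues, 1-based inclusive."""
    blocks = []
    start = None
    for i, c in enumerate(seq):
        if c in HYDROPHOBIC_RESIDUES:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_len:
                blocks.append((start + 1, i))
            start = None
    if start is not None and len(seq) - start >= min_len:
        blocks.append((start + 1, len(seq)))
    return blocks


def _random_block(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(HYDROPHOBIC_RESIDUES), size=length))


def _random_loop(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(LOOP_RESIDUES), size=length))


def make_templates(
    n_units: int = 2,
    block_len: int = DEFAULT_BLOCK_LEN,
    loop_len: int = DEFAULT_LOOP_LEN,
    seed: int = 0,
) -> list[UnitTemplate]:
    """Draw independent ancestral unit templates from one seeded stream.

    The PQ dipeptide replaces the last two residues of the first loop, so it
    sits just upstream of the first helix (inside the motif scan's flank).
    """
    if block_len < 15 or loop_len < 4:
        raise ValueError("block_len must be >= 15 and loop_len >= 4")
    rng = np.random.default_rng(seed)
    no_p = [c for c in LOOP_RESIDUES if c != "P"]
    templates = []
    for u in range(n_units):
        # the motif-bearing loop carries no other proline, so the planted PQ
        # is the unambiguous signature
        first_loop = "".join(rng.choice(no_p, size=loop_len - 2)) + "PQ"
        parts = [first_loop]
        for _ in range(3):
            parts.append(_random_block(rng, block_len))
            parts.append(_random_loop(rng, loop_len))
        templates.append(
            UnitTemplate(
                unit_id=f"U{u + 1}",
                sequence="".join(parts),
                pq_position=loop_len - 1,
            )
        )
    return templates


def plan_for_tmh_count(count: int, unit_id: str) -> tuple[PlanElement, ...]:
    """Expand a TMH count into a unit/linker plan by the greedy rule used for
    decomposition (triplet, then a linker when more triplets follow; 1-2
    trailing helices become trailing linkers)."""
    plan: list[PlanElement] = []
    for kind, idx in architecture._greedy_plan(count):
        if kind == "triplet":
            plan.append(("unit", unit_id))
        elif kind == "linker":
            plan.append(("linker", None))
        else:  # unresolved tail: emit one single-helix segment per helix
            plan.extend(("linker", None) for _ in idx)
    return tuple(plan)


def _expand_plan(
    arch, family_index: int, templates: Sequence[UnitTemplate]
) -> tuple[PlanElement, ...]:
    if isinstance(arch, int):
        unit = templates[family_index % len(templates)]
        return plan_for_tmh_count(arch, unit.unit_id)
    return tuple((kind, uid) for kind, uid in arch)


def plan_length(
    plan: Sequence[PlanElement],
    templates: Sequence[UnitTemplate],
    block_len: int = DEFAULT_BLOCK_LEN,
    loop_len: int = DEFAULT_LOOP_LEN,
) -> int:
    by_id = {t.unit_id: t for t in templates}
    total = 0
    for kind, uid in plan:
        if kind == "unit":
            total += len(by_id[uid].sequence)
        else:
            total += block_len + loop_len
    return total


def generate(
    scenario: EvolutionScenario, templates: Sequence[UnitTemplate]
) -> tuple[list[ProteinRecord], TruthTable]:
    """Simulate the scenario and return records plus planted truth.

    Deterministic: identical (scenario, templates) give byte-identical
    output. The PQ dipeptide of every unit is treated as implicitly
    invariant, since the screening stage filters on the motif.
    """
    if not templates:
        raise ValueError("generate requires at least one template")
    by_id = {t.unit_id: t for t in templates}
    rng = np.random.default_rng(scenario.seed)

    plans = []
    for f in range(scenario.n_families):
        plan = _expand_plan(scenario.architecture_per_family[f], f, templates)
        for kind, uid in plan:
            if kind == "unit" and uid not in by_id:
                raise ValueError(f"architecture plan references unknown template {uid!r}")
            if kind not in ("unit", "linker"):
                raise ValueError(f"unknown plan element kind {kind!r}")
        plans.append(plan)

    hydro = set(HYDROPHOBIC_RESIDUES)
    loop = set(LOOP_RESIDUES)
    counter = itertools.count(1)
    base_records: list[ProteinRecord] = []
    seq_rows: list[dict] = []
    fam_rows: list[dict] = []
    ancestors: dict[str, str] = {}

    for f, plan in enumerate(plans):
        family_id = f"FAM{f + 1}"
        taxon = TAXON_GROUPS[f % (len(TAXON_GROUPS) - 1)]  # skip "unknown"
        segments: list[str] = []
        seg_info: list[tuple[int, int, str]] = []  # (block_first, block_last, label)
        pq_positions: set[int] = set()
        pos = 0
        for kind, uid in plan:
            if kind == "unit":
                seg = by_id[uid].sequence
                pq = pos + by_id[uid].pq_position
                pq_positions.update({pq, pq + 1})
                label = f"unit:{uid}"
            else:
                seg = _random_block(rng, scenario.block_len) + _random_loop(
                    rng, scenario.loop_len
                )
                label = "linker"
            blocks = _hydrophobic_blocks(seg)
            seg_info.append((pos + blocks[0][0], pos + blocks[-1][1], label))
            segments.append(seg)
            pos += len(seg)
        ancestor = "".join(segments)
        # truth spans cut at the midpoints of the hydrophilic gaps between
        # consecutive elements' hydrophobic blocks (the same convention the
        # architecture stage uses for its loop-midpoint unit spans)
        cuts = [1]
        for (_, prev_end, _), (next_start, _, _) in zip(seg_info, seg_info[1:]):
            cuts.append((prev_end + next_start) // 2 + 1)
        cuts.append(len(ancestor) + 1)
        spans = [
            (cuts[k], cuts[k + 1] - 1, seg_info[k][2])
            for k in range(len(seg_info))
        ]
        if scenario.invariant_residue is not None:
            chars = list(ancestor)
            for col in scenario.invariant_columns:
                if col <= len(chars):
                    chars[col - 1] = scenario.invariant_residue
            ancestor = "".join(chars)
        ancestors[family_id] = ancestor
        n = len(ancestor)

        for col in scenario.invariant_columns:
            if not 1 <= col <= n:
                raise ValueError(f"invariant column {col} outside ancestor (len {n})")
        covary_cols: set[int] = set()
        for pair in scenario.covarying_pairs:
            for p in (pair.pos_a, pair.pos_b):
                if not 1 <= p <= n:
                    raise ValueError(f"covarying position {p} outside ancestor")
                covary_cols.add(p)

        protected = np.zeros(n, dtype=bool)
        for p in scenario.invariant_columns | pq_positions | covary_cols:
            protected[p - 1] = True

        tmh_count = sum(3 if kind == "unit" else 1 for kind, _ in plan)
        arch_class = architecture.classify(tmh_count)
        boundary_str = ";".join(f"{s}-{e}:{lab}" for s, e, lab in spans)

        for _ in range(scenario.seqs_per_family):
            seq = np.array(list(ancestor))
            mutate = (rng.random(n) < scenario.substitution_rate) & ~protected
            for i in np.flatnonzero(mutate):
                cur = seq[i]
                pool = hydro if cur in hydro else loop
                choices = sorted(pool - {cur})
                seq[i] = choices[rng.integers(len(choices))]
            for pair in scenario.covarying_pairs:
                a, b = pair.states[rng.integers(len(pair.states))]
                seq[pair.pos_a - 1] = a
                seq[pair.pos_b - 1] = b
            acc = f"SWT{next(counter):05d}"
            base_records.append(
                ProteinRecord(
                    accession=acc,
                    sequence="".join(seq),
                    description=f"synthetic {arch_class} {family_id}",
                    taxon_group=taxon,
                )
            )
            seq_rows.append(
                {
                    "accession": acc,
                    "family": family_id,
                    "tmh_count": tmh_count,
                    "arch_class": arch_class,
                    "unit_boundaries": boundary_str,
                    "is_fragment": False,
                    "duplicate_of": "",
                }
            )

        fam_rows.append(
            {
                "family": family_id,
                "ancestral_length": n,
                "plan": ",".join(
                    uid if kind == "unit" else "linker" for kind, uid in plan
                ),
                "invariant_columns": ",".join(
                    str(c) for c in sorted(scenario.invariant_columns)
                ),
                "pq_columns": ",".join(str(c) for c in sorted(pq_positions)),
                "covarying_pairs": ";".join(
                    f"{p.pos_a}:{p.pos_b}:" + "|".join(a + b for a, b in p.states)
                    for p in scenario.covarying_pairs
                ),
            }
        )

    records = list(base_records)
    n_base = len(records)

    n_frag = int(round(scenario.fragment_rate * n_base))
    if n_frag:
        frag_idx = rng.choice(n_base, size=n_frag, replace=False)
        for i in sorted(int(j) for j in frag_idx):
            full = records[i].sequence
            frac = rng.uniform(0.20, 0.45)
            flen = max(1, int(round(frac * len(full))))
            start = int(rng.integers(0, len(full) - flen + 1))
            records[i] = ProteinRecord(
                accession=records[i].accession,
                sequence=full[start : start + flen],
                description=records[i].description + " fragment",
                taxon_group=records[i].taxon_group,
            )
            seq_rows[i]["is_fragment"] = True

    n_dup = int(round(scenario.duplicate_rate * n_base))
    for _ in range(n_dup):
        src = int(rng.integers(n_base))
        acc = f"SWT{next(counter):05d}"
        records.append(
            ProteinRecord(
                accession=acc,
                sequence=records[src].sequence,
                description=records[src].description + " duplicate",
                taxon_group=records[src].taxon_group,
            )
        )
        row = dict(seq_rows[src])
        row["accession"] = acc
        row["duplicate_of"] = records[src].accession
        seq_rows.append(row)

    truth = TruthTable(
        sequences=pd.DataFrame(seq_rows),
        families=pd.DataFrame(fam_rows),
        ancestors=ancestors,
    )
    return records, truth


def loop_positions(
    plan: Sequence[PlanElement],
    templates: Sequence[UnitTemplate],
    block_len: int = DEFAULT_BLOCK_LEN,
    loop_len: int = DEFAULT_LOOP_LEN,
) -> list[int]:
    """1-based ancestral positions that lie in hydrophilic loops by
    construction (PQ motif positions excluded)."""
    by_id = {t.unit_id: t for t in templates}
    out: list[int] = []
    pos = 0
    for kind, uid in plan:
        if kind == "unit":
            t = by_id[uid]
            skip = {t.pq_position, t.pq_position + 1}
            for i, c in enumerate(t.sequence):
                if c not in HYDROPHOBIC_RESIDUES and (i + 1) not in skip:
                    out.append(pos + i + 1)
            pos += len(t.sequence)
        else:
            out.extend(pos + block_len + i + 1 for i in range(loop_len))
            pos += block_len + loop_len
    return out


def demo_scenario(
    seed: int = 0,
    n_families: int = 2,
    seqs_per_family: int = 20,
    substitution_rate: float = 0.1,
    n_invariant: int = 10,
    n_covarying: int = 2,
    fragment_rate: float = 0.0,
    duplicate_rate: float = 0.0,
    tmh_count: int = 7,
    templates: Sequence[UnitTemplate] | None = None,
) -> tuple[EvolutionScenario, list[UnitTemplate]]:
    """Standard two-family 7-TMH study scenario with planted sites.

    Invariant columns and covarying pairs are both placed in loop regions
    (so the planted tryptophans and charged covarying states do not perturb
    helix detection); covarying pairs use the default E/K compensatory
    table. Loop geometry is shared across templates, so the positions are
    valid for every family.
    """
    if templates is None:
        templates = make_templates(n_units=n_families, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    plan = plan_for_tmh_count(tmh_count, templates[0].unit_id)
    pool = list(loop_positions(plan, templates))
    pairs = []
    for _ in range(n_covarying):
        if len(pool) < 2:
            break
        a, b = sorted(
            int(p) for p in rng.choice(len(pool), size=2, replace=False)
        )
        pa, pb = pool[a], pool[b]
        pool = [p for p in pool if p not in (pa, pb)]
        pairs.append(CovaryingPair(pos_a=pa, pos_b=pb))
    inv_idx = rng.choice(len(pool), size=min(n_invariant, len(pool)), replace=False)
    inv = frozenset(int(pool[i]) for i in inv_idx)
    scenario = EvolutionScenario(
        n_families=n_families,
        seqs_per_family=seqs_per_family,
        architecture_per_family=tuple([tmh_count] * n_families),
        substitution_rate=substitution_rate,
        invariant_columns=inv,
        covarying_pairs=tuple(pairs),
        fragment_rate=fragment_rate,
        duplicate_rate=duplicate_rate,
        seed=seed,
    )
    return scenario, list(templates)
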