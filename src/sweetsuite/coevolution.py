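"""Column-pair mutual information (MI) with a shuffle-null z-score.

MI between two alignment columns measures how much knowing the residue at
one position predicts the residue at the other. Raw MI (natural log) is
computed from weighted, optionally pseudocounted joint frequencies over the
rows that carry a residue in both columns. Because raw MI depends on column
entropies and sample size, significance is assessed against an explicit
null: the rows of the second column are permuted ``n_shuffles`` times and
the z-score of the observed MI against that null distribution is reported.
Pairs with z above a threshold (default 6.5) are "significant"; they are
ranked into three display classes (top 5% red, down to the 70th percentile
black, remaining 70% gray), summed into per-column cumulative MI (cMI), and
optionally averaged over spatial neighbourhoods (proximity MI, pMI) when
structure coordinates are available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .msa import MSA, ReferenceMap, sequence_weights

DEFAULT_MI_THRESHOLD = 6.5
MIN_EFFECTIVE_ROWS = 5


@dataclass
class MIPair:
    col_a: int  # 1-based, col_a < col_b
    col_b: int
    mi_raw: float  # nats
    mi_z: float = float("nan")
    edge_class: str = ""

    @property
    def mi_bits(self) -> float:
        return self.mi_raw / math.log(2)


def _column_data(msa: MSA, weights: np.ndarray, gap_as_state: bool):
    cm = msa.column_matrix()
    if gap_as_state:
        # gaps become a 21st symbol; every row is "complete"
        cm = np.where(cm < 0, 20, cm)
    return cm


def _pair_mi(
    col_x: np.ndarray,
    col_y: np.ndarray,
    w: np.ndarray,
    pseudocount: float,
    n_states: int,
) -> float:
    joint = np.zeros((n_states, n_states))
    np.add.at(joint, (col_x, col_y), w)
    if pseudocount > 0:
        joint = joint + pseudocount
    total = joint.sum()
    if total <= 0:
        return 0.0
    p = joint / total
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    denom = np.outer(px, py)
    mi = float((p[nz] * np.log(p[nz] / denom[nz])).sum())
    return max(mi, 0.0)


def mutual_information(
    msa: MSA,
    pairs: Optional[Sequence[tuple[int, int]]] = None,
    pseudocount: float = 0.0,
    weighting: str = "none",
    gap_as_state: bool = False,
    min_effective_rows: int = MIN_EFFECTIVE_ROWS,
) -> list[MIPair]:
    """Raw MI (nats) for column pairs of the MSA.

    By default all pairs are scored; pass ``pairs`` (1-based, a < b) to
    restrict. Rows gapped in either column are excluded (pairwise-complete),
    unless ``gap_as_state`` treats the gap as a 21st symbol. Pairs where
    either column has fewer than ``min_effective_rows`` usable rows are
    skipped.
    """
    if msa.n_columns < 2:
        raise ValueError("mutual_information requires an MSA with >= 2 columns")
    w = sequence_weights(msa, weighting)
    cm = _column_data(msa, w, gap_as_state)
    n_states = 21 if gap_as_state else 20
    if pairs is None:
        pairs = list(itertools.combinations(range(1, msa.n_columns + 1), 2))
    out: list[MIPair] = []
    for a, b in pairs:
        if not (1 <= a < b <= msa.n_columns):
            raise ValueError(f"invalid column pair ({a}, {b})")
        ca, cb = cm[:, a - 1], cm[:, b - 1]
        ok = (ca >= 0) & (cb >= 0)
        if int(ok.sum()) < min_effective_rows:
            continue
        mi = _pair_mi(ca[ok], cb[ok], w[ok], pseudocount, n_states)
        out.append(MIPair(col_a=a, col_b=b, mi_raw=mi))
    return out


def mi_zscores(
    pairs: list[MIPair],
    msa: MSA,
    n_shuffles: int = 100,
    seed: int = 0,
    pseudocount: float = 0.0,
    weighting: str = "none",
    gap_as_state: bool = False,
) -> list[MIPair]:
    """Attach shuffle-null z-scores to MI pairs (in place; also returned).

    For each pair the rows of the second column are permuted
    ``n_shuffles`` times (one seeded stream, so results are reproducible);
    mi_z = (mi_raw - null mean) / null sd, with the sd floored at 1e-12.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be >= 20 for a usable null")
    rng = np.random.default_rng(seed)
    w = sequence_weights(msa, weighting)
    cm = _column_data(msa, w, gap_as_state)
    n_states = 21 if gap_as_state else 20
    for pair in pairs:
        ca, cb = cm[:, pair.col_a - 1], cm[:, pair.col_b - 1]
        ok = (ca >= 0) & (cb >= 0)
        x, y, ww = ca[ok], cb[ok], w[ok]
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            perm = rng.permutation(len(y))
            null[s] = _pair_mi(x, y[perm], ww[perm], pseudocount, n_states)
        sd = max(float(null.std(ddof=0)), 1e-12)
        pair.mi_z = (pair.mi_raw - float(null.mean())) / sd
    return pairs


def significant_pairs(
    pairs: Sequence[MIPair], mi_threshold: float = DEFAULT_MI_THRESHOLD
) -> list[MIPair]:
    return [p for p in pairs if p.mi_z > mi_threshold]


def classify_edges(significant: Sequence[MIPair]) -> list[MIPair]:
    """Three-class colouring of significant edges by raw MI rank.

    Ranked descending by mi_raw (ties by (col_a, col_b)): the top 5%
    (ceiling) are red, the next block down to the 70th percentile (floor of
    25%) black, and the remaining ~70% gray.
    """
    if not significant:
        raise ValueError("classify_edges requires at least one significant pair")
    ranked = sorted(significant, key=lambda p: (-p.mi_raw, p.col_a, p.col_b))
    n = len(ranked)
    n_red = math.ceil(0.05 * n)
    n_black = math.floor(0.25 * n)
    for i, pair in enumerate(ranked):
        if i < n_red:
            pair.edge_class = "red"
        elif i < n_red + n_black:
            pair.edge_class = "black"
        else:
            pair.edge_class = "gray"
    return ranked


def cumulative_mi(
    significant: Sequence[MIPair], n_columns: int
) -> np.ndarray:
    """cMI per column (1-based column c at index c-1): the sum of mi_raw over
    significant pairs containing c; 0 for columns in no significant pair."""
    cmi = np.zeros(n_columns)
    for p in significant:
        cmi[p.col_a - 1] += p.mi_raw
        cmi[p.col_b - 1] += p.mi_raw
    return cmi


@dataclass(frozen=True)
class StructureCoords:
    """Representative-atom coordinates keyed by reference residue number."""

    residues: tuple[int, ...]
    coords: np.ndarray  # (n, 3), Angstrom

    def __post_init__(self) -> None:
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("residue numbers must be unique")
        if self.coords.shape != (len(self.residues), 3):
            raise ValueError("coords must be (n_residues, 3)")

    @classmethod
    def from_table(cls, frame: pd.DataFrame) -> "StructureCoords":
        """Build from a table with columns residue, x, y, z."""
        return cls(
            residues=tuple(int(r) for r in frame["residue"]),
            coords=frame[["x", "y", "z"]].to_numpy(dtype=float),
        )


def proximity_mi(
    cmi: np.ndarray,
    coords: StructureCoords,
    reference_map: ReferenceMap,
    radius_angstrom: float = 5.0,
) -> pd.DataFrame:
    """Neighbourhood-averaged cMI on the structure.

    pMI(r) = mean cMI over residues within ``radius_angstrom`` of r
    (excluding r itself); residues without neighbours get 0. MSA columns
    whose reference residue has no coordinates are skipped.
    """
    res_to_col = reference_map.residue_to_column
    residues = [r for r in coords.residues if r in res_to_col]
    idx = [coords.residues.index(r) for r in residues]
    pts = coords.coords[idx]
    cmi_by_res = {
        r: cmi[res_to_col[r] - 1] if res_to_col[r] - 1 < len(cmi) else 0.0
        for r in residues
    }
    dmat = cdist(pts, pts)
    rows = []
    for i, r in enumerate(residues):
        neighbours = [
            residues[j]
            for j in range(len(residues))
            if j != i and dmat[i, j] <= radius_angstrom
        ]
        pmi = (
            float(np.mean([cmi_by_res[nb] for nb in neighbours]))
            if neighbours
            else 0.0
        )
        rows.append({"residue": r, "cMI": cmi_by_res[r], "pMI": pmi})
    return pd.DataFrame(rows)


def pair_table(
    pairs: Sequence[MIPair], reference_map: Optional[ReferenceMap] = None
) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "col_a": p.col_a,
                "col_b": p.col_b,
                "ref_a": reference_map.column_to_residue.get(p.col_a)
                if reference_map
                else None,
                "ref_b": reference_map.column_to_residue.get(p.col_b)
                if reference_map
                else None,
                "mi_nats": p.mi_raw,
                "mi_bits": p.mi_bits,
                "mi_z": p.mi_z,
                "class": p.edge_class,
            }
        )
    return pd.DataFrame(rows)
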