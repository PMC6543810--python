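"""Trajectory-level aggregation: interaction maps, persistent contacts and
binding-site occupancy.

The interaction map is a fragment x (residue, kind) table whose cells hold
the percentage of frames in which at least one interaction of that type
was observed — multiplicity within a frame does not count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .perception import InteractionRecord
from .trajectory import LigandFragmentMap, SiteDefinition, Trajectory

__all__ = [
    "InteractionMatrix",
    "OccupancyResult",
    "build_interaction_map",
    "persistent_contacts",
    "site_occupancy",
    "plot_interaction_map",
]


@dataclass
class InteractionMatrix:
    """Percentage-of-frames contact table.

    ``table`` is indexed by (residue_name, residue_number, chain_id, kind)
    with one column per ligand fragment; cells are percentages in [0, 100]
    over ``n_frames`` frames.
    """

    table: pd.DataFrame
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        vals = self.table.to_numpy(dtype=float)
        if vals.size and (vals.min() < 0 or vals.max() > 100):
            raise ValueError("cells must lie in [0, 100]")

    def cell(self, residue: tuple[str, int, str], kind: str, fragment: str) -> float:
        return float(self.table.loc[(residue[0], residue[1], residue[2], kind), fragment])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index = [f"{rn}{num}.{ch}:{kind}" for rn, num, ch, kind in out.index]
        out.to_csv(path, index_label="residue_kind")


def build_interaction_map(
    records: Iterable[InteractionRecord],
    fragments: LigandFragmentMap,
    n_frames: int,
) -> InteractionMatrix:
    """Aggregate per-frame records into the percentage-of-frames matrix.

    cell = 100 * |{frames with >=1 record of that (residue, kind,
    fragment)}| / n_frames.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    valid = set(fragments.names) | {"unassigned"}
    seen: set[tuple] = set()
    for rec in records:
        if rec.fragment_name not in valid:
            raise ValueError(f"record references unknown fragment {rec.fragment_name!r}")
        if not 0 <= rec.frame_index < n_frames:
            raise ValueError(f"record frame index {rec.frame_index} >= n_frames {n_frames}")
        seen.add((rec.partner, rec.kind, rec.fragment_name, rec.frame_index))
    counts: dict[tuple, int] = {}
    for partner, kind, frag, _ in seen:
        counts[(partner, kind, frag)] = counts.get((partner, kind, frag), 0) + 1
    rows = sorted({(p[0], p[1], p[2], k) for (p, k, _f) in counts})
    index = pd.MultiIndex.from_tuples(
        rows, names=["residue_name", "residue_number", "chain_id", "kind"]
    )
    cols = list(fragments.names)
    if any(f == "unassigned" for (_p, _k, f) in counts):
        cols.append("unassigned")
    table = pd.DataFrame(0.0, index=index, columns=cols)
    for (partner, kind, frag), c in counts.items():
        table.loc[(partner[0], partner[1], partner[2], kind), frag] = 100.0 * c / n_frames
    return InteractionMatrix(table=table, n_frames=n_frames)


def merge_interaction_maps(a: InteractionMatrix, b: InteractionMatrix) -> InteractionMatrix:
    """Frame-count-weighted combination of two maps over disjoint frame sets."""
    n = a.n_frames + b.n_frames
    ta = a.table.mul(a.n_frames / 100.0)
    tb = b.table.mul(b.n_frames / 100.0)
    combined = ta.add(tb, fill_value=0.0).mul(100.0 / n).sort_index()
    return InteractionMatrix(table=combined, n_frames=n)


def persistent_contacts(matrix: InteractionMatrix, threshold_pct: float) -> pd.DataFrame:
    """Contacts above a persistence threshold, most persistent first.

    Returns a DataFrame (fragment, residue_name, residue_number, chain_id,
    kind, pct) sorted by pct descending then residue number ascending.
    """
    if not 0 <= threshold_pct <= 100:
        raise ValueError("threshold_pct must lie in [0, 100]")
    rows = []
    for (rn, num, ch, kind), series in matrix.table.iterrows():
        for frag, pct in series.items():
            if pct > threshold_pct:
                rows.append(
                    {
                        "fragment": frag,
                        "residue_name": rn,
                        "residue_number": num,
                        "chain_id": ch,
                        "kind": kind,
                        "pct": float(pct),
                    }
                )
    out = pd.DataFrame(
        rows, columns=["fragment", "residue_name", "residue_number", "chain_id", "kind", "pct"]
    )
    if len(out):
        out = out.sort_values(
            ["pct", "residue_number"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return out


@dataclass
class OccupancyResult:
    bound: np.ndarray  # bool per frame
    fraction: float
    start_ns: float
    end_ns: float
    duration_ns: float

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must lie in [0, 1]")
        if abs(self.duration_ns - (self.end_ns - self.start_ns)) > 1e-9:
            raise ValueError("duration must equal end - start")


def _longest_run(mask: np.ndarray) -> tuple[int, int] | None:
    best: tuple[int, int] | None = None
    start = None
    for i, b in enumerate(mask):
        if b and start is None:
            start = i
        elif not b and start is not None:
            if best is None or i - start > best[1] - best[0]:
                best = (start, i - 1)
            start = None
    if start is not None:
        i = len(mask)
        if best is None or i - start > best[1] - best[0]:
            best = (start, i - 1)
    return best


def site_occupancy(
    traj: Trajectory,
    ligand_atom_ids: Sequence[int],
    site: SiteDefinition,
) -> OccupancyResult:
    """Per-frame bound flag and longest contiguous residence interval.

    A frame is bound when the minimum heavy-atom distance between the
    ligand selection and the site residues is within the site's cutoff.
    n contiguous bound frames at spacing dt span (n-1)*dt.
    """
    ligand_atom_ids = list(ligand_atom_ids)
    if not ligand_atom_ids:
        raise ValueError("ligand selection is empty")
    lig_idx = traj.indices_of(ligand_atom_ids)
    lig_idx = np.array(
        [i for i in lig_idx if traj.atoms[i].element.upper() != "H"], dtype=int
    )
    site_idx = np.array(
        [
            i
            for i, a in enumerate(traj.atoms)
            if a.chain_id == site.chain_id
            and a.residue_number in site.residue_numbers
            and a.element.upper() != "H"
            and not a.is_ligand
        ],
        dtype=int,
    )
    if site_idx.size == 0:
        raise ValueError("site residues not found in topology")
    lig = traj.coords[:, lig_idx]  # (f, nl, 3)
    rec = traj.coords[:, site_idx]  # (f, nr, 3)
    d = np.linalg.norm(lig[:, :, None, :] - rec[:, None, :, :], axis=3)
    mindist = d.reshape(traj.n_frames, -1).min(axis=1)
    bound = mindist <= site.cutoff
    fraction = float(bound.mean())
    run = _longest_run(bound)
    if run is None:
        return OccupancyResult(bound=bound, fraction=0.0, start_ns=0.0, end_ns=0.0, duration_ns=0.0)
    start_t = float(traj.times[run[0]])
    end_t = float(traj.times[run[1]])
    return OccupancyResult(
        bound=bound,
        fraction=fraction,
        start_ns=start_t,
        end_ns=end_t,
        duration_ns=end_t - start_t,
    )


def plot_interaction_map(matrix: InteractionMatrix, path) -> None:
    """Render the contact table as a heat map (percent of frames)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = matrix.table
    fig, ax = plt.subplots(
        figsize=(1.2 * len(table.columns) + 3, 0.4 * len(table) + 2)
    )
    im = ax.imshow(table.to_numpy(), aspect="auto", cmap="YlOrRd", vmin=0, vmax=100)
    ax.set_xticks(range(len(table.columns)), table.columns)
    ax.set_yticks(
        range(len(table)),
        [f"{rn}{num}.{ch} {kind}" for rn, num, ch, kind in table.index],
    )
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            v = table.iloc[i, j]
            if v > 0:
                ax.text(j, i, f"{v:.0f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="% of frames")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
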