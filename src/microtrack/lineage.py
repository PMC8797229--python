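"""Cell geometry, per-cell features and generation-level statistics.

Length of a rod is defined as the geodesic length of its skeleton path
between the two skeleton endpoints, extended by the mean half-width at each
end (other tools use e.g. the bounding-ellipse major axis; the definitions
differ by a roughly constant offset for rods).  The growth rate over one
generation is the average of the per-step relative length increments
(L_t - L_{t-1}) / L_{t-1} / dt, in 1/hr; a generation runs from birth
(the frame after the mother's division) to the frame before the cell's own
division, and cells observed for fewer than three frames are excluded from
growth statistics to reduce noise.

Pole-age statistics group generation growth rates by the cells' O/N pole
history; groups of equal history length are compared with a two-sided
t-test (one letter) or a one-way ANOVA with Tukey post-hoc (two or more
letters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, sparse, stats
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

__all__ = [
    "cell_endpoints",
    "cell_length",
    "fluorescence",
    "growth_rate",
    "generation_growth_rates",
    "aggregate_by_pole_history",
    "PoleAgeReport",
    "check_lineage_integrity",
]


def _skeleton_graph(skel: np.ndarray):
    pts = np.argwhere(skel)
    index = -np.ones(skel.shape, dtype=np.int64)
    index[tuple(pts.T)] = np.arange(len(pts))
    rows, cols, vals = [], [], []
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1)]
    for dr, dc in offs:
        nb = pts + (dr, dc)
        ok = ((nb[:, 0] >= 0) & (nb[:, 0] < skel.shape[0])
              & (nb[:, 1] >= 0) & (nb[:, 1] < skel.shape[1]))
        src = np.arange(len(pts))[ok]
        dst = index[tuple(nb[ok].T)]
        hit = dst >= 0
        rows.extend(src[hit])
        cols.extend(dst[hit])
        vals.extend([np.hypot(dr, dc)] * int(hit.sum()))
    g = sparse.coo_matrix((vals, (rows, cols)), shape=(len(pts), len(pts)))
    return pts, (g + g.T).tocsr()


def _skeleton_path(mask: np.ndarray):
    """Endpoints and geodesic length of the skeleton path (tree-diameter
    style: farthest point from an arbitrary start, then farthest from
    there).  Returns None when the skeleton has fewer than 2 pixels."""
    skel = skeletonize(mask)
    if skel.sum() < 2:
        return None
    pts, graph = _skeleton_graph(skel)
    d0 = dijkstra(graph, indices=0, directed=False)
    d0[~np.isfinite(d0)] = -1
    a = int(np.argmax(d0))
    da = dijkstra(graph, indices=a, directed=False)
    da[~np.isfinite(da)] = -1
    b = int(np.argmax(da))
    return pts[a].astype(float), pts[b].astype(float), float(da[b])


def cell_endpoints(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """The two pole-end points of a cell mask, as (row, col) floats.

    Extremal points of the skeleton path; falls back to extreme projections
    on the principal axis when the skeleton degenerates to a point.  Returns
    None for masks too small to orient (< 2 pixels).
    """
    mask = np.asarray(mask, dtype=bool)
    res = _skeleton_path(mask)
    if res is not None:
        return res[0], res[1]
    pts = np.argwhere(mask)
    if len(pts) < 2:
        return None
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    return pts[np.argmin(proj)].astype(float), pts[np.argmax(proj)].astype(float)


def cell_length(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Pole-to-pole cell length in physical units (see module docstring).

    A degenerate skeleton (single point) falls back to the equivalent-circle
    diameter of the mask area.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("cell mask must contain at least 2 pixels")
    res = _skeleton_path(mask)
    if res is None:
        return 2.0 * np.sqrt(mask.sum() / np.pi) * pixel_size
    a, b, path = res
    edt = ndimage.distance_transform_edt(mask)
    cap = edt[int(a[0]), int(a[1])] + edt[int(b[0]), int(b[1])]
    return (path + cap) * pixel_size


def fluorescence(mask: np.ndarray, channel_frame: np.ndarray) -> float:
    """Mean channel intensity over the cell's pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    return float(np.asarray(channel_frame, dtype=np.float64)[mask].mean())


def growth_rate(lengths: np.ndarray, dt_hr: float) -> float:
    """Average per-step relative elongation rate over one generation, 1/hr.

    Note this is the discrete estimator (L_t - L_{t-1}) / L_{t-1} / dt: for
    exact exponential growth at rate r it returns (e^{r dt} - 1)/dt, i.e.
    the discretisation bias is part of the definition, not corrected.
    """
    if dt_hr <= 0:
        raise ValueError("dt_hr must be positive")
    lengths = np.asarray(lengths, dtype=np.float64)
    if len(lengths) < 2:
        return np.nan
    steps = np.diff(lengths) / lengths[:-1] / dt_hr
    return float(steps.mean())


def generation_growth_rates(
    features: pd.DataFrame,
    dt_hr: float,
    min_frames: int = 3,
    min_first_frame_cutoff: int | None = None,
) -> pd.DataFrame:
    """One row per cell: its generation growth rate and pole history.

    ``features`` holds (cell_id, frame, length_um, pole_history) rows; a
    cell's rows span exactly its generation (birth to just before its own
    division), so the rate is computed over all of them.  Cells present for
    fewer than ``min_frames`` frames are excluded; with
    ``min_first_frame_cutoff``, cells first seen after that frame are
    excluded too (cells entering the field late carry noisy rates).
    """
    rows = []
    for cell_id, grp in features.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        if len(grp) < min_frames:
            continue
        if (min_first_frame_cutoff is not None
                and grp["frame"].iloc[0] > min_first_frame_cutoff):
            continue
        rows.append({
            "cell_id": cell_id,
            "n_frames": len(grp),
            "pole_history": grp["pole_history"].iloc[-1],
            "growth_rate": growth_rate(grp["length_um"].to_numpy(), dt_hr),
        })
    return pd.DataFrame(rows, columns=["cell_id", "n_frames", "pole_history",
                                       "growth_rate"])


@dataclass
class PoleAgeReport:
    groups: pd.DataFrame          # per history: n, mean, sem
    tests: pd.DataFrame           # per generation: test, statistic, p-value
    tukey: dict[int, object]      # generation -> statsmodels Tukey result


def aggregate_by_pole_history(
    features: pd.DataFrame,
    dt_hr: float,
    min_frames: int = 3,
    max_generation: int = 3,
) -> PoleAgeReport:
    """Group generation growth rates by pole history and test for
    old-pole/new-pole differences.

    Histories of equal length are compared together: generation 1 (single
    letter) with a two-sided unpaired t-test O vs N, generations >= 2 with
    a one-way ANOVA plus Tukey HSD post-hoc.  Groups with n < 2 are dropped
    with a warning.  Cells with empty histories (pole age not yet
    observable) are excluded.
    """
    per_cell = generation_growth_rates(features, dt_hr, min_frames=min_frames)
    per_cell = per_cell[(per_cell["pole_history"] != "")
                        & np.isfinite(per_cell["growth_rate"])]
    grp_rows, test_rows, tukey = [], [], {}
    for hist, grp in per_cell.groupby("pole_history"):
        grp_rows.append({
            "pole_history": hist, "generation": len(hist),
            "n": len(grp), "mean": grp["growth_rate"].mean(),
            "sem": stats.sem(grp["growth_rate"]) if len(grp) > 1 else np.nan,
        })
    groups = pd.DataFrame(grp_rows, columns=["pole_history", "generation",
                                             "n", "mean", "sem"])
    for gen in range(1, max_generation + 1):
        sub = per_cell[per_cell["pole_history"].str.len() == gen]
        samples = {h: g["growth_rate"].to_numpy()
                   for h, g in sub.groupby("pole_history")}
        small = [h for h, v in samples.items() if len(v) < 2]
        if small:
            warnings.warn(f"generation {gen}: dropping groups with n < 2: "
                          f"{small}")
            samples = {h: v for h, v in samples.items() if len(v) >= 2}
        if len(samples) < 2:
            continue
        if gen == 1:
            o = samples.get("O")
            n = samples.get("N")
            if o is None or n is None:
                continue
            t, p = stats.ttest_ind(o, n)
            test_rows.append({"generation": gen, "test": "t-test",
                              "statistic": float(t), "p_value": float(p)})
        else:
            f, p = stats.f_oneway(*samples.values())
            test_rows.append({"generation": gen, "test": "anova",
                              "statistic": float(f), "p_value": float(p)})
            from statsmodels.stats.multicomp import pairwise_tukeyhsd
            values = np.concatenate(list(samples.values()))
            labels = np.concatenate([[h] * len(v)
                                     for h, v in samples.items()])
            tukey[gen] = pairwise_tukeyhsd(values, labels)
    tests = pd.DataFrame(test_rows, columns=["generation", "test",
                                             "statistic", "p_value"])
    return PoleAgeReport(groups=groups, tests=tests, tukey=tukey)


def check_lineage_integrity(lineage: pd.DataFrame) -> None:
    """Assert referential integrity of a lineage table.

    Every non-founder's mother exists; daughters' first frame is the
    mother's last frame + 1; ancestry is acyclic; pole histories extend the
    mother's by at most one letter.  Raises AssertionError on violation.
    """
    by_id = lineage.set_index("cell_id")
    for cid, row in by_id.iterrows():
        mid = row["mother_id"]
        if mid is None or (isinstance(mid, (int, np.integer)) and mid < 0):
            continue
        assert mid in by_id.index, f"cell {cid}: unknown mother {mid}"
        mrow = by_id.loc[mid]
        assert row["first_frame"] == mrow["last_frame"] + 1, (
            f"cell {cid}: first frame {row['first_frame']} != mother "
            f"{mid} last frame {mrow['last_frame']} + 1")
        mh = mrow["pole_history"] or ""
        ch = row["pole_history"] or ""
        assert len(ch) <= len(mh) + 1, (
            f"cell {cid}: history {ch!r} grew by more than one letter "
            f"from {mh!r}")
        if len(ch) == len(mh) + 1:
            assert ch[:-1] == mh, (
                f"cell {cid}: history {ch!r} does not extend mother's {mh!r}")
        # acyclicity: walk up with a step bound
        seen = {cid}
        cur = mid
        for _ in range(len(by_id) + 1):
            if cur is None or (isinstance(cur, (int, np.integer)) and cur < 0):
                break
            assert cur not in seen, f"ancestry cycle at cell {cur}"
            seen.add(cur)
            cur = by_id.loc[cur, "mother_id"]
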