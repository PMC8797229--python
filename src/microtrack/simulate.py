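"""Agent-based simulator of rod-shaped bacterial microcolonies.

Cells are 2-D spherocylinders (capsules) that elongate exponentially,
divide stochastically around a sampled division length, and push each other
apart through a simple pairwise-repulsion relaxation.  Frames are rendered
with a phase-contrast-like appearance (bright background, dark cell
interiors, a bright halo around each cell, Gaussian blur and sensor noise)
plus optional per-strain fluorescence channels, and every frame comes with
complete ground truth: label masks, frame-to-frame assignments, and a
lineage table with pole-age bookkeeping.

Pole bookkeeping follows the standard old/new-pole convention: at a
division the two poles formed at the septum are "new" and the inherited
ends are "old".  Founders start with poles of unknown age; their first
division initialises pole tracking but appends no O/N letter, because a
letter records which of the *mother's* poles (old vs new) a daughter
inherited and that is undefined for a mother with age-unknown poles.  From
then on every division appends exactly one letter to each daughter:
'O' for the daughter keeping the mother's old pole, 'N' for its sibling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import LabelMask, Movie

__all__ = [
    "CellAgent",
    "SimConfig",
    "DivisionEvent",
    "SimResult",
    "step_colony",
    "relax_overlaps",
    "render_frame",
    "run_colony",
    "render_movie",
    "emit_ground_truth",
    "simulate",
]


@dataclass
class CellAgent:
    """One rod-shaped cell: a capsule of total length ``length`` (pole tip to
    pole tip) and diameter ``width``, centred at ``center`` (row, col in um).

    ``pole_old_sign`` marks which axis end (+1 or -1 along the orientation
    unit vector) is the old pole; it is meaningful only when
    ``poles_assigned`` is True (i.e. after the cell's lineage has seen at
    least one division)."""

    id: int
    center: np.ndarray          # (row, col) um
    orientation: float          # radians
    length: float               # um, tip to tip; length >= width
    width: float                # um
    elongation_rate: float      # 1/hr
    division_length: float      # um, sampled threshold
    strain: str = "wt"
    mother_id: int | None = None
    pole_history: str = ""
    poles_assigned: bool = False
    pole_old_sign: int = +1
    birth_frame: int = 0

    @property
    def axis_half(self) -> float:
        """Half of the straight axis between the two cap centres."""
        return max(self.length - self.width, 0.0) / 2.0

    @property
    def direction(self) -> np.ndarray:
        return np.array([np.sin(self.orientation), np.cos(self.orientation)])

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """The two axis endpoints (cap centres), (+1 side, -1 side)."""
        u = self.direction
        return self.center + self.axis_half * u, self.center - self.axis_half * u

    @property
    def pole_old(self) -> np.ndarray | None:
        if not self.poles_assigned:
            return None
        e_plus, e_minus = self.endpoints()
        return e_plus if self.pole_old_sign > 0 else e_minus

    @property
    def pole_new(self) -> np.ndarray | None:
        if not self.poles_assigned:
            return None
        e_plus, e_minus = self.endpoints()
        return e_minus if self.pole_old_sign > 0 else e_plus


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Growth parameters emulate *E. coli* microcolonies on minimal-medium
    agarose pads imaged every 5 minutes at 100x (0.129 um/px): mean
    elongation rate 0.6 1/hr, division around 4.5 um with ~10% variability,
    near-symmetric division.  ``old_pole_penalty`` multiplies the elongation
    rate of daughters that inherit an old pole by (1 - penalty); the default
    0 gives a null colony for calibration tests."""

    seed: int = 0
    n_founders: int = 2
    n_frames: int = 30
    interval_min: float = 5.0
    field_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.129
    # growth / division
    mean_elongation_rate: float = 0.6   # 1/hr
    elongation_cv: float = 0.10
    division_length_mean: float = 4.5   # um
    division_cv: float = 0.10
    division_asymmetry_sd: float = 0.02
    cell_width_um: float = 1.0
    founder_length_range: tuple[float, float] = (2.5, 3.8)
    orientation_jitter_sd: float = 0.03  # rad per division
    old_pole_penalty: float = 0.0
    # mechanics
    mechanics: bool = True
    relax_tol_um: float = 0.05
    relax_max_iter: int = 60
    # rendering
    background: float = 0.7
    interior_contrast: float = 0.45
    halo_amplitude: float = 0.25
    halo_sigma_um: float = 0.25
    blur_sigma_px: float = 1.0
    noise_sigma: float = 0.02
    drift_per_frame_px: tuple[float, float] | None = None
    # strains: name -> {"growth": multiplier, "fluor": {channel: level}}
    strain_table: dict = field(default_factory=lambda: {"wt": {"growth": 1.0,
                                                               "fluor": {}}})
    founder_strains: tuple[str, ...] | None = None

    def fluor_channels(self) -> list[str]:
        chans: list[str] = []
        for spec in self.strain_table.values():
            for ch in spec.get("fluor", {}):
                if ch not in chans:
                    chans.append(ch)
        return chans


@dataclass
class DivisionEvent:
    frame: int           # first frame on which the daughters exist
    mother_id: int
    daughter_old: int    # daughter keeping the mother's +old-side end
    daughter_new: int


@dataclass
class SimResult:
    config: SimConfig
    trace: list[list[CellAgent]]          # per-frame agent snapshots
    events: list[DivisionEvent]
    movie: Movie | None = None
    masks: LabelMask | None = None
    registry: list[dict[int, int]] | None = None   # per frame: label -> cell id


# ---------------------------------------------------------------------------
# growth and division


def _sample_rate(cfg: SimConfig, rng: np.random.Generator, strain: str,
                 last_letter: str | None) -> float:
    mult = cfg.strain_table.get(strain, {}).get("growth", 1.0)
    base = cfg.mean_elongation_rate * mult
    if last_letter == "O":
        base *= 1.0 - cfg.old_pole_penalty
    if cfg.elongation_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.elongation_cv**2))
        base *= rng.lognormal(-sigma**2 / 2, sigma)
    return base


def _sample_division_length(cfg: SimConfig, rng: np.random.Generator) -> float:
    if cfg.division_cv <= 0:
        return cfg.division_length_mean
    sigma = np.sqrt(np.log1p(cfg.division_cv**2))
    return cfg.division_length_mean * rng.lognormal(-sigma**2 / 2, sigma)


def step_colony(
    agents: list[CellAgent],
    dt: float,
    rng: np.random.Generator,
    config: SimConfig,
    *,
    next_id: int | None = None,
    frame: int = 0,
) -> tuple[list[CellAgent], list[DivisionEvent], int]:
    """Advance the colony by ``dt`` hours.

    Each cell elongates by exp(rate * dt); cells over their sampled division
    threshold split at mid-length (plus asymmetry noise) into two daughters
    whose lengths sum to the mother's length minus one cap width (the septum
    consumes one cap).  Returns (new agents, division events, next free id).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if next_id is None:
        next_id = 1 + max((a.id for a in agents), default=-1)
    out: list[CellAgent] = []
    events: list[DivisionEvent] = []
    for cell in agents:
        grown = replace(cell, length=cell.length * np.exp(cell.elongation_rate * dt))
        if grown.length < grown.division_length:
            out.append(grown)
            continue
        d_old, d_new = _divide(grown, rng, config, next_id, frame)
        events.append(DivisionEvent(frame=frame, mother_id=grown.id,
                                    daughter_old=d_old.id, daughter_new=d_new.id))
        next_id += 2
        out.extend([d_old, d_new])
    if config.mechanics:
        relax_overlaps(out, tol=config.relax_tol_um,
                       max_iter=config.relax_max_iter)
    return out, events, next_id


def _divide(mother: CellAgent, rng: np.random.Generator, cfg: SimConfig,
            next_id: int, frame: int) -> tuple[CellAgent, CellAgent]:
    w = mother.width
    total = mother.length - w          # daughters' summed length
    f = 0.5 + (rng.normal(0.0, cfg.division_asymmetry_sd)
               if cfg.division_asymmetry_sd > 0 else 0.0)
    f = float(np.clip(f, 0.25, 0.75))
    len_old = max(total * f, w)
    len_new = max(total - len_old, w)

    u = mother.direction
    s = mother.pole_old_sign if mother.poles_assigned else +1
    # tip of the old-pole side, pulled in by w/2 so the pair stays centred
    tip_old = mother.center + s * (mother.length / 2.0 - w / 2.0) * u
    c_old = tip_old - s * (len_old / 2.0) * u
    c_new = tip_old - s * (len_old + len_new / 2.0) * u

    if mother.poles_assigned:
        hist_old = mother.pole_history + "O"
        hist_new = mother.pole_history + "N"
    else:  # founder's first division: poles become tracked, no letter yet
        hist_old = hist_new = ""

    def make(idx: int, center: np.ndarray, length: float, sign: int,
             hist: str) -> CellAgent:
        last = hist[-1] if hist else None
        jitter = (rng.normal(0.0, cfg.orientation_jitter_sd)
                  if cfg.orientation_jitter_sd > 0 else 0.0)
        return CellAgent(
            id=idx,
            center=center.copy(),
            orientation=mother.orientation + jitter,
            length=length,
            width=w,
            elongation_rate=_sample_rate(cfg, rng, mother.strain, last),
            division_length=_sample_division_length(cfg, rng),
            strain=mother.strain,
            mother_id=mother.id,
            pole_history=hist,
            poles_assigned=True,
            pole_old_sign=sign,
            birth_frame=frame,
        )

    d_old = make(next_id, c_old, len_old, s, hist_old)
    d_new = make(next_id + 1, c_new, len_new, -s, hist_new)
    return d_old, d_new


# ---------------------------------------------------------------------------
# mechanics


def _segment_distance(p1, q1, p2, q2):
    """Closest distance between segments p1-q1 and p2-q2, and the
    connecting unit vector from segment 1 to segment 2."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    EPS = 1e-12
    if a <= EPS and e <= EPS:
        s = t = 0.0
    elif a <= EPS:
        s = 0.0
        t = np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= EPS:
            t = 0.0
            s = np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > EPS else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t = 1.0
                s = np.clip((b - c) / a, 0.0, 1.0)
    cp1 = p1 + s * d1
    cp2 = p2 + t * d2
    diff = cp2 - cp1
    dist = float(np.linalg.norm(diff))
    if dist < 1e-9:
        # coincident axes: push apart sideways
        n = np.array([d1[1], -d1[0]])
        nn = np.linalg.norm(n)
        n = n / nn if nn > 1e-9 else np.array([1.0, 0.0])
        return 0.0, n
    return dist, diff / dist


def relax_overlaps(agents: list[CellAgent], tol: float = 0.05,
                   max_iter: int = 60) -> int:
    """Iteratively translate overlapping capsules apart along the vector
    joining their closest points until the worst overlap is below ``tol``
    (um).  Returns the number of iterations used."""
    if len(agents) < 2:
        return 0
    for it in range(max_iter):
        centers = np.array([a.center for a in agents])
        reach = np.array([a.length / 2.0 for a in agents])
        tree = cKDTree(centers)
        pairs = tree.query_pairs(2.0 * reach.max(), output_type="ndarray")
        worst = 0.0
        moves = np.zeros_like(centers)
        ends = [a.endpoints() for a in agents]
        for i, j in pairs:
            dist, n = _segment_distance(ends[i][0], ends[i][1],
                                        ends[j][0], ends[j][1])
            overlap = (agents[i].width + agents[j].width) / 2.0 - dist
            if overlap > 0:
                worst = max(worst, overlap)
                moves[i] -= 0.5 * overlap * n
                moves[j] += 0.5 * overlap * n
        if worst <= tol:
            return it
        for a, m in zip(agents, moves):
            a.center = a.center + m
    return max_iter


# ---------------------------------------------------------------------------
# rendering


def _capsule_distance_field(agent: CellAgent, shape: tuple[int, int],
                            pixel_size: float, offset: np.ndarray,
                            margin_um: float):
    """Distance (um) from pixel centres to the agent's axis segment, on the
    agent's bounding box.  Returns (rows slice, cols slice, dist array) or
    None when the box misses the field."""
    e1, e2 = agent.endpoints()
    pad = agent.width / 2.0 + margin_um
    lo = np.minimum(e1, e2) - pad - offset
    hi = np.maximum(e1, e2) + pad - offset
    r0 = max(int(np.floor(lo[0] / pixel_size - 0.5)), 0)
    c0 = max(int(np.floor(lo[1] / pixel_size - 0.5)), 0)
    r1 = min(int(np.ceil(hi[0] / pixel_size + 0.5)) + 1, shape[0])
    c1 = min(int(np.ceil(hi[1] / pixel_size + 0.5)) + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return None
    rows = (np.arange(r0, r1) + 0.5) * pixel_size + offset[0]
    cols = (np.arange(c0, c1) + 0.5) * pixel_size + offset[1]
    py, px = np.meshgrid(rows, cols, indexing="ij")
    d = e2 - e1
    dd = d @ d
    if dd < 1e-12:
        dist = np.hypot(py - e1[0], px - e1[1])
    else:
        t = ((py - e1[0]) * d[0] + (px - e1[1]) * d[1]) / dd
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(py - (e1[0] + t * d[0]), px - (e1[1] + t * d[1]))
    return slice(r0, r1), slice(c0, c1), dist


def render_frame(
    agents: Iterable[CellAgent],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    drift_um: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray, dict[int, int]]:
    """Render one frame.

    Returns (phase image in [0,1], fluorescence images, label mask,
    label -> agent id registry).  ``drift_um`` shifts the world-to-pixel
    mapping, emulating stage drift; masks and images shift together.
    """
    if config.pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    H, W = config.field_px
    ps = config.pixel_size_um
    offset = np.zeros(2) if drift_um is None else np.asarray(drift_um, float)

    dist_min = np.full((H, W), np.inf)
    labels = np.zeros((H, W), dtype=np.int32)
    registry: dict[int, int] = {}
    margin = 4.0 * config.halo_sigma_um
    next_label = 1
    for agent in agents:
        res = _capsule_distance_field(agent, (H, W), ps, offset, margin)
        if res is None:
            continue
        rs, cs, dist = res
        inside = dist <= agent.width / 2.0
        if inside.any():
            lab = next_label
            next_label += 1
            registry[lab] = agent.id
            sub = labels[rs, cs]
            claim = inside & (dist < dist_min[rs, cs])
            sub[claim] = lab
            labels[rs, cs] = sub
        closer = dist < dist_min[rs, cs]
        dist_min[rs, cs] = np.where(closer, dist, dist_min[rs, cs])

    half_w = config.cell_width_um / 2.0
    phase = np.full((H, W), config.background)
    interior = dist_min <= half_w
    if interior.any():
        rel = np.zeros((H, W))
        rel[interior] = np.sqrt(np.clip(1.0 - (dist_min[interior] / half_w) ** 2,
                                        0.0, 1.0))
        phase -= config.interior_contrast * rel
    outside = (~interior) & np.isfinite(dist_min)
    if outside.any():
        halo = np.zeros((H, W))
        halo[outside] = config.halo_amplitude * np.exp(
            -((dist_min[outside] - half_w) / config.halo_sigma_um) ** 2)
        phase += halo
    if config.blur_sigma_px > 0:
        phase = ndimage.gaussian_filter(phase, config.blur_sigma_px,
                                        mode="reflect")
    if rng is not None and config.noise_sigma > 0:
        phase = phase + rng.normal(0.0, config.noise_sigma, phase.shape)
    phase = np.clip(phase, 0.0, 1.0)

    fluor: dict[str, np.ndarray] = {}
    agent_by_id = {a.id: a for a in agents}
    for ch in config.fluor_channels():
        img = np.zeros((H, W))
        for lab, aid in registry.items():
            level = config.strain_table.get(agent_by_id[aid].strain, {}) \
                .get("fluor", {}).get(ch, 0.0)
            if level:
                img[labels == lab] = level
        if config.blur_sigma_px > 0:
            img = ndimage.gaussian_filter(img, config.blur_sigma_px,
                                          mode="reflect")
        if rng is not None and config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, img.shape)
        fluor[ch] = np.clip(img, 0.0, None)
    return phase, fluor, labels, registry


# ---------------------------------------------------------------------------
# full runs and ground truth


def _founders(cfg: SimConfig, rng: np.random.Generator) -> list[CellAgent]:
    H, W = cfg.field_px
    extent = np.array([H, W]) * cfg.pixel_size_um
    strains = cfg.founder_strains or tuple(
        list(cfg.strain_table)[i % len(cfg.strain_table)]
        for i in range(cfg.n_founders))
    agents = []
    for i in range(cfg.n_founders):
        center = extent * (0.25 + 0.5 * rng.random(2))
        lo, hi = cfg.founder_length_range
        agents.append(CellAgent(
            id=i,
            center=center,
            orientation=rng.uniform(0, np.pi),
            length=rng.uniform(lo, hi),
            width=cfg.cell_width_um,
            elongation_rate=_sample_rate(cfg, rng, strains[i], None),
            division_length=_sample_division_length(cfg, rng),
            strain=strains[i],
            birth_frame=0,
        ))
    if cfg.mechanics:
        relax_overlaps(agents, tol=cfg.relax_tol_um, max_iter=cfg.relax_max_iter)
    return agents


def run_colony(config: SimConfig,
               rng: np.random.Generator | None = None) -> SimResult:
    """Run growth/division/mechanics only (no rendering)."""
    rng = rng or np.random.default_rng(config.seed)
    agents = _founders(config, rng)
    trace = [[replace(a, center=a.center.copy()) for a in agents]]
    events: list[DivisionEvent] = []
    next_id = len(agents)
    dt = config.interval_min / 60.0
    for t in range(1, config.n_frames):
        agents, ev, next_id = step_colony(agents, dt, rng, config,
                                          next_id=next_id, frame=t)
        events.extend(ev)
        trace.append([replace(a, center=a.center.copy()) for a in agents])
    return SimResult(config=config, trace=trace, events=events)


def render_movie(result: SimResult,
                 rng: np.random.Generator | None = None) -> SimResult:
    """Render a completed trace into a Movie + LabelMask + registry."""
    cfg = result.config
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    drift = np.zeros(2)
    step = (np.array(cfg.drift_per_frame_px, float) * cfg.pixel_size_um
            if cfg.drift_per_frame_px is not None else None)
    phase_frames, mask_frames, registries = [], [], []
    fluor_frames: dict[str, list[np.ndarray]] = {ch: [] for ch in cfg.fluor_channels()}
    for t, agents in enumerate(result.trace):
        if step is not None and t > 0:
            drift = drift + step
        phase, fluor, labels, reg = render_frame(agents, cfg, rng,
                                                 drift_um=drift)
        phase_frames.append(phase)
        mask_frames.append(labels)
        registries.append(reg)
        for ch in fluor_frames:
            fluor_frames[ch].append(fluor[ch])
    data = {"phase": np.stack(phase_frames)}
    for ch, frames in fluor_frames.items():
        data[ch] = np.stack(frames)
    result.movie = Movie(data=data, phase_channel="phase",
                         interval_min=cfg.interval_min,
                         pixel_size_um=cfg.pixel_size_um)
    result.masks = LabelMask(frames=mask_frames)
    result.registry = registries
    return result


def emit_ground_truth(result: SimResult) -> tuple[LabelMask, list[dict], pd.DataFrame]:
    """Ground truth from a rendered simulation.

    Returns (masks, tracking ground truth, lineage table).  The tracking GT
    is one dict per frame transition t-1 -> t mapping each frame-(t-1) label
    to ``("continues", label)``, ``("divides", label_old_side, label_new_side)``
    or ``("exited", None)``.
    """
    if result.masks is None or result.registry is None:
        raise ValueError("simulation has not been rendered; call render_movie")
    cfg = result.config
    events_by_mother: dict[tuple[int, int], DivisionEvent] = {
        (e.frame, e.mother_id): e for e in result.events}

    tracking: list[dict] = []
    for t in range(1, len(result.trace)):
        prev_reg = result.registry[t - 1]
        curr_reg = result.registry[t]
        id_to_label = {aid: lab for lab, aid in curr_reg.items()}
        frame_map: dict[int, tuple] = {}
        for lab, aid in prev_reg.items():
            if aid in id_to_label:
                frame_map[lab] = ("continues", id_to_label[aid])
                continue
            ev = events_by_mother.get((t, aid))
            if ev is not None:
                l_old = id_to_label.get(ev.daughter_old)
                l_new = id_to_label.get(ev.daughter_new)
                if l_old is not None and l_new is not None:
                    frame_map[lab] = ("divides", l_old, l_new)
                elif l_old is not None or l_new is not None:
                    frame_map[lab] = ("continues",
                                      l_old if l_old is not None else l_new)
                else:
                    frame_map[lab] = ("exited", None)
            else:
                frame_map[lab] = ("exited", None)
        tracking.append(frame_map)

    rows = []
    seen: dict[int, dict] = {}
    for t, agents in enumerate(result.trace):
        visible = ({aid for aid in result.registry[t].values()}
                   if result.registry is not None else {a.id for a in agents})
        for a in agents:
            if a.id not in visible:
                continue
            rec = seen.setdefault(a.id, {
                "cell_id": a.id,
                "mother_id": a.mother_id if a.mother_id is not None else -1,
                "first_frame": t, "last_frame": t,
                "pole_history": a.pole_history,
                "strain": a.strain,
                "elongation_rate": a.elongation_rate,
            })
            rec["last_frame"] = t
    daughters: dict[int, list[int]] = {}
    for e in result.events:
        daughters.setdefault(e.mother_id, []).extend(
            [e.daughter_old, e.daughter_new])
    for rec in seen.values():
        ds = daughters.get(rec["cell_id"], [])
        rec["daughter1"] = ds[0] if len(ds) > 0 else -1
        rec["daughter2"] = ds[1] if len(ds) > 1 else -1
        rows.append(rec)
    lineage = pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)
    return result.masks, tracking, lineage


def trace_to_feature_table(result: SimResult) -> pd.DataFrame:
    """Flat (cell, frame) table straight from the agent trace (true lengths,
    no imaging).  Used for statistics at colony sizes where rendering every
    frame would be wasteful."""
    rows = []
    dt_hr = result.config.interval_min / 60.0
    for t, agents in enumerate(result.trace):
        for a in agents:
            rows.append({
                "cell_id": a.id, "frame": t,
                "length_um": a.length,
                "pole_history": a.pole_history,
                "mother_id": a.mother_id if a.mother_id is not None else -1,
                "strain": a.strain,
            })
    df = pd.DataFrame(rows)
    df.attrs["interval_hr"] = dt_hr
    return df


def simulate(config: SimConfig) -> SimResult:
    """Run and render a full synthetic movie with ground truth."""
    rng = np.random.default_rng(config.seed)
    result = run_colony(config, rng)
    return render_movie(result, rng)
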