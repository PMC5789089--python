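"""Detection, tracking, filtering and classification of endocytic events.

The pipeline mirrors how live-cell pol-TIRF movies are analyzed:

1. bias-subtract using a closed-shutter dark-frame average,
2. (optionally) register channels with an affine transform fitted to
   fiducial bead positions, applied to spot coordinates,
3. detect diffraction-limited clathrin spots per frame (band-pass filter,
   local maxima above a robust MAD threshold, centroid refinement) and link
   them into tracks by nearest-neighbor assignment with gap closing,
4. extract per-channel intensity traces at each track position (disc sum
   minus a local annulus background; the P/S ratio trace is formed from the
   raw disc sums since the planar membrane is signal, not background),
5. filter to complete, isolated events carrying a dynamin signature,
6. classify each event by the timing of the membrane-bending (P/S) onset
   relative to clathrin assembly: coincident onsets -> class 1; a clathrin
   plateau before bending -> class 2; continued clathrin recruitment during
   bending -> class 3,
7. summarize per-class lifetimes and inter-channel lags.

All frame indices are 0-based; times are frame * frame_interval. Positions
use array coordinates: x along the first image axis, y along the second,
origin at the top-left pixel center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import linear_sum_assignment

from .onsets import detect_onset, detect_end, robust_baseline
from .stacks import ChannelStack

__all__ = [
    "AffineTransform2D",
    "RawTrack",
    "EventTrack",
    "TrackParams",
    "FilterCriteria",
    "bias_calibrate",
    "bias_subtract",
    "fit_affine",
    "detect_and_track",
    "extract_traces",
    "filter_events",
    "classify_event",
    "cohort_stats",
    "correlate_height_ps",
    "analyze_movie",
    "match_to_truth",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def bias_calibrate(dark_stack: np.ndarray) -> np.ndarray:
    """Per-pixel camera bias: the mean of a closed-shutter dark-frame stack."""
    dark = np.asarray(dark_stack, dtype=float)
    if dark.ndim == 2:
        dark = dark[None]
    if dark.ndim != 3 or dark.shape[0] < 1:
        raise ValueError("dark stack must be (n_frames, H, W) with >= 1 frame")
    return dark.mean(axis=0)


def bias_subtract(stack: ChannelStack, bias: np.ndarray) -> ChannelStack:
    """Subtract the bias image from every frame/channel, clipping at zero."""
    if bias.shape != stack.frames.shape[-2:]:
        raise ValueError(
            f"bias shape {bias.shape} does not match frames {stack.frames.shape[-2:]}"
        )
    frames = np.clip(stack.frames - bias[None, None], 0.0, None)
    return ChannelStack(frames, stack.channels, stack.pixel_size, stack.frame_interval)


@dataclass
class AffineTransform2D:
    """2D affine map ``p -> A p + b`` fitted to fiducial point pairs."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    rms: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform2D(inv, -inv @ self.offset)


def fit_affine(points_src: np.ndarray, points_dst: np.ndarray) -> AffineTransform2D:
    """Least-squares affine transform mapping src fiducials onto dst.

    Requires >= 3 non-collinear pairs; the returned transform carries the
    residual RMS (over all coordinates) of the fit.
    """
    src = np.atleast_2d(np.asarray(points_src, dtype=float))
    dst = np.atleast_2d(np.asarray(points_dst, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("point sets must be matching (n, 2) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise ValueError("source points are collinear")
    design = np.column_stack([src, np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = coef[:2].T
    offset = coef[2]
    resid = dst - (src @ matrix.T + offset)
    rms = float(np.sqrt(np.mean(resid**2)))
    return AffineTransform2D(matrix, offset, rms)


# ---------------------------------------------------------------------------
# spot detection and tracking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackParams:
    """Spot-detection and linking parameters (pixels / frames)."""

    sigma_small: float = 1.0  # band-pass inner scale ~ PSF sigma in px
    sigma_large: float = 4.0  # band-pass outer scale for background removal
    k: float = 5.0  # detection threshold in MAD units above the median
    refine_half: int = 2  # centroid refinement half-window
    search_radius: float = 3.0  # max per-frame displacement for linking
    gap_frames: int = 2  # close gaps up to this many missed frames
    min_length: int = 2


@dataclass
class RawTrack:
    """A linked sequence of spot detections (one spot per covered frame)."""

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def start(self) -> int:
        return int(self.frames[0])

    @property
    def end(self) -> int:
        return int(self.frames[-1])

    @property
    def x_med(self) -> float:
        return float(np.median(self.x))

    @property
    def y_med(self) -> float:
        return float(np.median(self.y))


def _detect_spots(img: np.ndarray, params: TrackParams) -> np.ndarray:
    """Band-pass + local-maximum spot candidates refined by center of mass;
    returns an (n, 2) array of positions."""
    bp = ndimage.gaussian_filter(img, params.sigma_small) - ndimage.gaussian_filter(
        img, params.sigma_large
    )
    med = np.median(bp)
    mad = np.median(np.abs(bp - med)) * 1.4826
    thresh = med + params.k * max(mad, 1e-12)
    maxima = (ndimage.maximum_filter(bp, size=3) == bp) & (bp > thresh)
    coords = np.argwhere(maxima)
    h = params.refine_half
    out = []
    for cx, cy in coords:
        x0, x1 = max(0, cx - h), min(img.shape[0], cx + h + 1)
        y0, y1 = max(0, cy - h), min(img.shape[1], cy + h + 1)
        win = bp[x0:x1, y0:y1] - thresh
        win = np.clip(win, 0, None)
        tot = win.sum()
        if tot <= 0:
            out.append((float(cx), float(cy)))
            continue
        xs, ys = np.mgrid[x0:x1, y0:y1]
        out.append((float((xs * win).sum() / tot), float((ys * win).sum() / tot)))
    return np.array(out).reshape(-1, 2)


def detect_and_track(
    stack: ChannelStack, channel: str = "clathrin", params: TrackParams | None = None
) -> list[RawTrack]:
    """Detect spots in one channel per frame and link them into tracks.

    Linking is globally optimal per frame (Hungarian assignment on pairwise
    distances, capped at ``search_radius``); a track survives up to
    ``gap_frames`` missed frames before it is closed.
    """
    if params is None:
        params = TrackParams()
    movie = stack.channel(channel)
    if movie.shape[0] < 2:
        raise ValueError("need at least 2 frames to track")

    active: list[dict] = []  # each: frames, xs, ys, last_frame
    done: list[dict] = []
    for f in range(movie.shape[0]):
        spots = _detect_spots(movie[f], params)
        # drop tracks that exceeded the gap allowance
        still = []
        for tr in active:
            if f - tr["last"] > params.gap_frames + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        if len(spots) and len(active):
            heads = np.array([[tr["xs"][-1], tr["ys"][-1]] for tr in active])
            dist = np.linalg.norm(heads[:, None, :] - spots[None, :, :], axis=2)
            cost = np.where(dist <= params.search_radius, dist, 1e6)
            rows, cols = linear_sum_assignment(cost)
            used = set()
            for r, c in zip(rows, cols):
                if cost[r, c] < 1e5:
                    tr = active[r]
                    tr["frames"].append(f)
                    tr["xs"].append(spots[c, 0])
                    tr["ys"].append(spots[c, 1])
                    tr["last"] = f
                    used.add(c)
            new_idx = [c for c in range(len(spots)) if c not in used]
        else:
            new_idx = list(range(len(spots)))
        for c in new_idx:
            active.append(
                {
                    "frames": [f],
                    "xs": [spots[c, 0]],
                    "ys": [spots[c, 1]],
                    "last": f,
                }
            )
    done.extend(active)
    tracks = []
    tid = 0
    for tr in done:
        if len(tr["frames"]) < params.min_length:
            continue
        tracks.append(
            RawTrack(
                tid,
                np.asarray(tr["frames"]),
                np.asarray(tr["xs"]),
                np.asarray(tr["ys"]),
            )
        )
        tid += 1
    return tracks


# ---------------------------------------------------------------------------
# trace extraction
# ---------------------------------------------------------------------------


@dataclass
class EventTrack:
    """Per-event time series and derived classification quantities.

    ``intensity`` holds full-movie background-subtracted traces per channel;
    ``raw`` the disc sums without background subtraction (used for the P/S
    ratio, where the planar membrane is the legitimate denominator);
    ``ps`` the ratio trace. Onset/end frames, lifetimes (s) and lags (s)
    are filled by :func:`classify_event`.
    """

    track_id: int
    x: float
    y: float
    start: int
    end: int
    frame_interval: float
    intensity: dict[str, np.ndarray]
    raw: dict[str, np.ndarray]
    ps: np.ndarray
    out_of_bounds: np.ndarray | None = None
    onsets: dict[str, int | None] = field(default_factory=dict)
    ends: dict[str, int | None] = field(default_factory=dict)
    class_label: str = "unclassified"
    reject_reason: str | None = None
    clathrin_lifetime: float = np.nan
    ps_lifetime: float = np.nan
    dynamin_lifetime: float = np.nan
    lag_cl_to_ps: float = np.nan
    lag_cl_to_dyn: float = np.nan
    lag_ps_to_dyn: float = np.nan


def _disc_annulus(shape, cx, cy, r_sig, r_bg_in, r_bg_out):
    x0 = max(0, int(np.floor(cx - r_bg_out)))
    x1 = min(shape[0], int(np.ceil(cx + r_bg_out)) + 1)
    y0 = max(0, int(np.floor(cy - r_bg_out)))
    y1 = min(shape[1], int(np.ceil(cy + r_bg_out)) + 1)
    xs, ys = np.mgrid[x0:x1, y0:y1]
    rr = (xs - cx) ** 2 + (ys - cy) ** 2
    return (x0, x1, y0, y1), rr <= r_sig**2, (rr > r_bg_in**2) & (rr <= r_bg_out**2)


def extract_traces(
    stack: ChannelStack,
    track: RawTrack,
    r_sig: float = 3.0,
    r_bg_in: float = 4.0,
    r_bg_out: float = 6.0,
    ps_floor: float = 1e-3,
) -> EventTrack:
    """Full-movie intensity traces at a track's (median, stationary) position.

    Per channel and frame: signal = disc sum (radius ``r_sig``) minus the
    annulus median times the disc pixel count. The P/S trace divides the raw
    P and S disc sums (floor-clipped), since the flat membrane contributes
    the planar ratio rather than zero. Expects a bias-subtracted stack.
    """
    cx, cy = track.x_med, track.y_med
    shape = stack.frames.shape[-2:]
    (x0, x1, y0, y1), disc, annulus = _disc_annulus(
        shape, cx, cy, r_sig, r_bg_in, r_bg_out
    )
    full_disc_px = int(np.ceil(np.pi * r_sig**2)) - 1  # nominal interior count
    clipped = disc.sum() < full_disc_px
    box = stack.frames[:, :, x0:x1, y0:y1]  # (T, C, h, w)
    disc_sums = box[:, :, disc].sum(axis=2)  # (T, C)
    ann_med = np.median(box[:, :, annulus], axis=2) if annulus.any() else 0.0
    n_disc = disc.sum()
    intensity, raw = {}, {}
    for ci, name in enumerate(stack.channels):
        raw[name] = disc_sums[:, ci]
        intensity[name] = disc_sums[:, ci] - (
            ann_med[:, ci] * n_disc if annulus.any() else 0.0
        )
    if "P" in raw and "S" in raw:
        ps = raw["P"] / np.maximum(raw["S"], ps_floor)
    else:
        ps = np.full(stack.n_frames, np.nan)
    oob = np.full(stack.n_frames, clipped)
    return EventTrack(
        track_id=track.track_id,
        x=cx,
        y=cy,
        start=track.start,
        end=track.end,
        frame_interval=stack.frame_interval,
        intensity=intensity,
        raw=raw,
        ps=ps,
        out_of_bounds=oob if clipped else None,
    )


# ---------------------------------------------------------------------------
# event filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterCriteria:
    """Selection rules for isolated, complete endocytic events."""

    min_duration: int = 5  # frames
    iso_radius: float = 5.0  # px
    require_dynamin: bool = True
    baseline_window: int = 10
    k: float = 3.0
    m: int = 3


def filter_events(
    tracks: Sequence[EventTrack],
    criteria: FilterCriteria | None = None,
    n_frames: int | None = None,
) -> tuple[list[EventTrack], list[EventTrack]]:
    """Keep complete, isolated, dynamin-positive events.

    Rejection reasons (the first failed criterion is the primary reason):
    ``censored`` (touches the movie start/end), ``too_short``,
    ``not_isolated`` (another track within the isolation radius during the
    lifetime), ``no_dynamin``. Kept and rejected partition the input.
    """
    if criteria is None:
        criteria = FilterCriteria()
    kept, rejected = [], []
    for tr in tracks:
        last_frame = (n_frames - 1) if n_frames is not None else None
        reason = None
        if tr.start == 0 or (last_frame is not None and tr.end >= last_frame):
            reason = "censored"
        elif tr.end - tr.start + 1 < criteria.min_duration:
            reason = "too_short"
        else:
            for other in tracks:
                if other.track_id == tr.track_id:
                    continue
                if other.end < tr.start or other.start > tr.end:
                    continue
                if np.hypot(other.x - tr.x, other.y - tr.y) <= criteria.iso_radius:
                    reason = "not_isolated"
                    break
        if reason is None and criteria.require_dynamin and "dynamin" in tr.intensity:
            # anchor the search to the track span (as in classify_event)
            off = max(0, tr.start - criteria.baseline_window - 2)
            dyn_on = detect_onset(
                tr.intensity["dynamin"][off:],
                baseline_window=criteria.baseline_window,
                k=criteria.k,
                m=criteria.m,
                start=max(0, tr.start - criteria.m - off),
            )
            if dyn_on is None:
                reason = "no_dynamin"
            else:
                tr.onsets["dynamin"] = dyn_on + off
        if reason is None:
            kept.append(tr)
        else:
            tr.reject_reason = reason
            tr.class_label = "rejected"
            rejected.append(tr)
    return kept, rejected


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_event(
    track: EventTrack,
    coincidence_window: int = 2,
    baseline_window: int = 10,
    k: float = 3.0,
    m: int = 3,
    alpha: float = 0.05,
    rel_increase: float = 0.10,
    bend_window: int = 12,
) -> str:
    """Assign a membrane-bending class from the clathrin and P/S onsets.

    Class 1 if the P/S onset falls within ``coincidence_window`` frames of
    the clathrin onset; otherwise class 2 if the clathrin trace shows no
    significant further increase over the bending interval (one-sided slope
    test at ``alpha`` over at most ``bend_window`` frames from the P/S
    onset, or fitted relative increase below ``rel_increase`` of the
    pre-bending plateau), else class 3. Tracks without a P/S onset are
    labelled abortive; without a clathrin onset, rejected. Lifetimes and
    lags are stored on the track as a side effect.

    Onset searches are anchored to the detected track span: the baseline
    window is taken from the frames immediately preceding the track start,
    and the clathrin search begins just before it — an unrestricted search
    over the whole movie accumulates spurious threshold crossings. The
    bending-onset search additionally starts no earlier than the clathrin
    onset minus the coincidence window, since membrane curvature preceding
    clathrin is not part of the event model.
    """
    dt = track.frame_interval
    cl = track.intensity["clathrin"]
    # offset so the baseline window ends just before the track begins
    off = max(0, track.start - baseline_window - 2)

    def onset(trace, start):
        res = detect_onset(
            trace[off:], baseline_window=baseline_window, k=k, m=m,
            start=max(0, start - off),
        )
        return None if res is None else res + off

    def end_of(trace, on):
        return (
            detect_end(trace[off:], on - off, baseline_window=baseline_window, k=k, m=m)
            + off
        )

    cl_on = onset(cl, max(0, track.start - m))
    if cl_on is None:
        track.class_label = "rejected"
        track.reject_reason = "no_clathrin_onset"
        return track.class_label
    cl_end = end_of(cl, cl_on)
    track.onsets["clathrin"] = cl_on
    track.ends["clathrin"] = cl_end
    track.clathrin_lifetime = (cl_end - cl_on - 1) * dt

    ps_on = onset(track.ps, max(0, cl_on - coincidence_window))
    if ps_on is not None:
        # refinement may backtrack past the search start; curvature preceding
        # clathrin is outside the event model, so clamp to the window start
        ps_on = max(ps_on, cl_on - coincidence_window)
    if ps_on is None:
        track.class_label = "abortive"
        return track.class_label
    ps_end = end_of(track.ps, ps_on)
    track.onsets["PS"] = ps_on
    track.ends["PS"] = ps_end
    track.ps_lifetime = (ps_end - ps_on - 1) * dt
    track.lag_cl_to_ps = (ps_on - cl_on) * dt

    dyn_on = track.onsets.get("dynamin")
    if dyn_on is None and "dynamin" in track.intensity:
        dyn_on = onset(track.intensity["dynamin"], max(0, cl_on - coincidence_window))
        track.onsets["dynamin"] = dyn_on
    if dyn_on is not None:
        dyn_end = end_of(track.intensity["dynamin"], dyn_on)
        track.ends["dynamin"] = dyn_end
        track.dynamin_lifetime = (dyn_end - dyn_on - 1) * dt
        track.lag_cl_to_dyn = (dyn_on - cl_on) * dt
        track.lag_ps_to_dyn = (dyn_on - ps_on) * dt

    if abs(ps_on - cl_on) <= coincidence_window:
        track.class_label = "class1"
        return track.class_label

    seg = cl[ps_on : min(cl_end, ps_on + bend_window) + 1]
    if len(seg) < 3:
        track.class_label = "class2"
        return track.class_label
    xs = np.arange(len(seg), dtype=float)
    res = stats.linregress(xs, seg)
    p_one = res.pvalue / 2.0 if res.slope > 0 else 1.0 - res.pvalue / 2.0
    # reference level: the pre-bending clathrin plateau
    pre = cl[max(cl_on, ps_on - 3) : ps_on]
    plateau = max(float(np.mean(pre)) if len(pre) else float(np.mean(seg)), 1e-9)
    fitted_increase = res.slope * (len(seg) - 1) / plateau
    if p_one > alpha or fitted_increase < rel_increase:
        track.class_label = "class2"
    else:
        track.class_label = "class3"
    return track.class_label


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------


def events_table(tracks: Sequence[EventTrack]) -> pd.DataFrame:
    """One row per classified event (positions, class, lifetimes, lags)."""
    rows = []
    for tr in tracks:
        rows.append(
            {
                "track_id": tr.track_id,
                "x": tr.x,
                "y": tr.y,
                "start": tr.start,
                "end": tr.end,
                "class_label": tr.class_label,
                "reject_reason": tr.reject_reason,
                "clathrin_onset": tr.onsets.get("clathrin"),
                "ps_onset": tr.onsets.get("PS"),
                "dynamin_onset": tr.onsets.get("dynamin"),
                "clathrin_lifetime": tr.clathrin_lifetime,
                "ps_lifetime": tr.ps_lifetime,
                "dynamin_lifetime": tr.dynamin_lifetime,
                "lag_cl_to_ps": tr.lag_cl_to_ps,
                "lag_cl_to_dyn": tr.lag_cl_to_dyn,
                "lag_ps_to_dyn": tr.lag_ps_to_dyn,
            }
        )
    return pd.DataFrame(rows)


def cohort_stats(
    tracks: Sequence[EventTrack] | pd.DataFrame, test: str = "mannwhitney"
) -> dict:
    """Per-class lifetime / lag summary and the class-1 vs class-2/3
    clathrin-lifetime comparison.

    Returns a dict with ``per_class`` (DataFrame: n, mean and SD of each
    lifetime and lag per class), ``lifetime_test`` (statistic and p-value of
    the two-sided Mann-Whitney U by default, Welch's t as an option), and
    ``lag_differences`` (class-2/3 minus class-1 mean lags).
    """
    df = tracks if isinstance(tracks, pd.DataFrame) else events_table(tracks)
    if not len(df):
        raise ValueError("no classified tracks")
    cols = [
        "clathrin_lifetime",
        "ps_lifetime",
        "dynamin_lifetime",
        "lag_cl_to_ps",
        "lag_cl_to_dyn",
        "lag_ps_to_dyn",
    ]
    agg = df.groupby("class_label")[cols].agg(["count", "mean", "std"])
    g1 = df.loc[df["class_label"] == "class1", "clathrin_lifetime"].dropna()
    g23 = df.loc[df["class_label"].isin(["class2", "class3"]), "clathrin_lifetime"].dropna()
    if len(g1) and len(g23):
        if test == "mannwhitney":
            res = stats.mannwhitneyu(g1, g23, alternative="two-sided")
            lifetime_test = {"test": "mannwhitney", "stat": float(res.statistic), "p": float(res.pvalue)}
        elif test == "welch":
            res = stats.ttest_ind(g1, g23, equal_var=False)
            lifetime_test = {"test": "welch", "stat": float(res.statistic), "p": float(res.pvalue)}
        else:
            raise ValueError(f"unknown test {test!r}")
    else:
        lifetime_test = {"test": test, "stat": np.nan, "p": np.nan}
    lag_diffs = {}
    for lag in ("lag_cl_to_ps", "lag_cl_to_dyn", "lag_ps_to_dyn"):
        m1 = df.loc[df["class_label"] == "class1", lag].dropna()
        m23 = df.loc[df["class_label"].isin(["class2", "class3"]), lag].dropna()
        lag_diffs[lag] = (
            float(m23.mean() - m1.mean()) if len(m1) and len(m23) else np.nan
        )
    return {"per_class": agg, "lifetime_test": lifetime_test, "lag_differences": lag_diffs}


def correlate_height_ps(
    heights: np.ndarray,
    ps_values: np.ndarray,
    n_permutations: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rank correlation between structure heights and P/S with a
    permutation p-value (two-sided, seeded)."""
    h = np.asarray(heights, dtype=float)
    p = np.asarray(ps_values, dtype=float)
    if h.shape != p.shape or h.ndim != 1:
        raise ValueError("heights and ps_values must be equal-length 1D arrays")
    if len(h) < 4:
        raise ValueError("need at least 4 paired samples")
    if np.ptp(h) == 0 or np.ptp(p) == 0:
        raise ValueError("correlation undefined for constant input")
    rho = float(stats.spearmanr(h, p).statistic)
    rng = np.random.default_rng(seed)
    rh = stats.rankdata(h)
    rp = stats.rankdata(p)
    # Spearman rho = Pearson on ranks; permute one ranking
    def pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float((a @ b) / np.sqrt((a @ a) * (b @ b)))

    count = 0
    for _ in range(n_permutations):
        if abs(pearson(rh, rng.permutation(rp))) >= abs(rho) - 1e-12:
            count += 1
    pval = (count + 1) / (n_permutations + 1)
    return rho, pval


# ---------------------------------------------------------------------------
# end-to-end pipeline and ground-truth matching
# ---------------------------------------------------------------------------


def analyze_movie(
    stack: ChannelStack,
    bias: np.ndarray | None = None,
    track_params: TrackParams | None = None,
    criteria: FilterCriteria | None = None,
    coincidence_window: int = 2,
    r_sig: float = 3.0,
) -> tuple[pd.DataFrame, list[EventTrack], dict]:
    """Run the full pipeline on a movie; returns (events table, all event
    tracks including rejected ones, cohort summary)."""
    if bias is not None:
        stack = bias_subtract(stack, bias)
    raw_tracks = detect_and_track(stack, "clathrin", track_params)
    traces = [extract_traces(stack, t, r_sig=r_sig) for t in raw_tracks]
    kept, rejected = filter_events(traces, criteria, n_frames=stack.n_frames)
    for tr in kept:
        classify_event(tr, coincidence_window=coincidence_window)
    all_tracks = kept + rejected
    table = events_table(all_tracks)
    classified = [t for t in kept if t.class_label.startswith("class")]
    summary = cohort_stats(classified) if classified else {}
    return table, all_tracks, summary


def match_to_truth(
    events: pd.DataFrame,
    truth: pd.DataFrame,
    max_dist: float = 2.0,
) -> pd.DataFrame:
    """Match analyzed events to ground-truth events by position (within
    ``max_dist`` px) and overlapping time; returns truth joined with the
    matched event columns (suffix ``_det``), NaN where unmatched."""
    det = events.copy()
    rows = []
    used = set()
    for _, t in truth.iterrows():
        best, best_d = None, np.inf
        for idx, e in det.iterrows():
            if idx in used:
                continue
            d = np.hypot(e["x"] - t["x_px"], e["y"] - t["y_px"])
            if d > max_dist or d >= best_d:
                continue
            # require time overlap between track span and truth event span
            if e["end"] < t["clathrin_onset_frame"] or e["start"] > t["end_frame"]:
                continue
            best, best_d = idx, d
        row = dict(t)
        if best is not None:
            used.add(best)
            for c in det.columns:
                row[f"{c}_det"] = det.loc[best, c]
        rows.append(row)
    return pd.DataFrame(rows)


def track_recovery(
    tracks: Sequence[RawTrack], truth: pd.DataFrame, max_dist: float = 2.0
) -> float:
    """Fraction of non-abortive ground-truth events matched by a raw track
    (within ``max_dist`` px of the truth position and overlapping in time)."""
    t_sub = truth[truth["class_label"] != "abortive"]
    hits = 0
    for _, t in t_sub.iterrows():
        for tr in tracks:
            if (
                np.hypot(tr.x_med - t["x_px"], tr.y_med - t["y_px"]) <= max_dist
                and tr.end >= t["clathrin_onset_frame"]
                and tr.start <= t["end_frame"]
            ):
                hits += 1
                break
    return hits / max(len(t_sub), 1)
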