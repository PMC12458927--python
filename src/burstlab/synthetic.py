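"""Ground-truthed synthetic inputs for every pipeline stage.

Four generators emulate the data the analysis modules consume:

* :func:`simulate_telegraph_trace` — live-cell transcription-site intensity
  traces from a two-state (telegraph) promoter, with the true ON/OFF state
  per frame.
* :func:`simulate_smfish_field` — a two-channel smFISH field (exon, intron)
  with nucleus/cytoplasm label masks and a ground-truth spot table.
* :func:`simulate_population_trajectories` — fraction-transcribing time
  courses for sorted populations relaxing to equilibrium, with binomial
  sampling noise.
* :func:`simulate_gene_universe` — gene lists with a planted overlap on a
  common universe.

Every generator is a pure function of its spec (including the seed):
identical inputs give bit-identical outputs.  Child RNGs for independent
sub-tasks are split from the spec seed with ``numpy`` ``spawn`` semantics via
``default_rng(seed).spawn`` so adding one consumer never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relaxation import a_eq as _a_eq
from .relaxation import relax as _relax

__all__ = [
    "TelegraphParams",
    "FieldSpec",
    "TrajectorySpec",
    "TelegraphTrace",
    "SmfishField",
    "GeneUniverse",
    "simulate_telegraph_trace",
    "simulate_smfish_field",
    "simulate_population_trajectories",
    "simulate_gene_universe",
    "total_duration_hours",
]

SPOT_COLUMNS = ["channel", "x", "y", "intensity", "cell_id", "compartment"]


def total_duration_hours(n_frames: int, dt: float) -> float:
    """Movie duration in hours for ``n_frames`` frames at interval ``dt`` seconds."""
    return n_frames * dt / 3600.0


# ---------------------------------------------------------------------------
# telegraph traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TelegraphParams:
    """Two-state promoter simulation parameters.

    Rates are per minute; ``dt`` is the frame interval in seconds.  Defaults
    follow a typical live-cell imaging session: one frame every 100 s for
    512 frames (14.2 h).
    """

    k_on: float = 0.15  # OFF -> ON events/min
    k_off: float = 0.023  # ON -> OFF events/min
    intensity_per_rna: float = 100.0  # a.u. per nascent RNA
    mean_nascent: float = 2.0  # nascent RNAs during active periods
    noise_sd: float = 20.0  # additive Gaussian sd, a.u.
    dt: float = 100.0  # s between frames
    n_frames: int = 512
    seed: int = 0

    def __post_init__(self):
        for name in ("k_on", "k_off"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class TelegraphTrace:
    """A simulated trace plus its ground truth.

    ``intensity`` is the observed per-frame signal; ``states`` the true
    binary promoter state at each frame midpoint; ``switch_times`` the exact
    event times (minutes) of the underlying continuous-time process, with
    ``initial_state`` the state before the first switch.
    """

    intensity: np.ndarray
    states: np.ndarray
    switch_times: np.ndarray
    initial_state: int
    params: TelegraphParams

    @property
    def dwell_times(self) -> np.ndarray:
        """Exact dwell durations (minutes) of the underlying process.

        All entries are full exponential draws: the first dwell starts at
        t=0 (a fresh draw, valid by memorylessness of the stationary start)
        and the last extends past the recording end, so no length-biased
        truncation enters.
        """
        return np.diff(self.switch_times)

    @property
    def dwell_states(self) -> np.ndarray:
        """State occupied during each dwell of :attr:`dwell_times`."""
        n = len(self.dwell_times)
        return (self.initial_state + np.arange(n)) % 2

    def to_frame(self, allele_id: int = 0, population: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "allele_id": allele_id,
                "frame": np.arange(len(self.intensity)),
                "intensity": self.intensity,
                "true_state": self.states,
            }
        )
        if population is not None:
            df["population"] = population
        return df


def simulate_telegraph_trace(params: TelegraphParams) -> TelegraphTrace:
    """Simulate one telegraph trace sampled at frame midpoints.

    The promoter switches OFF->ON at ``k_on`` and ON->OFF at ``k_off``
    (exact event-driven simulation with exponential dwells); the state
    reported for frame i is the state at time (i + 1/2) dt, which avoids
    aliasing bias for dwells near the frame interval.  The initial state is
    drawn from the stationary distribution.  Observed intensity is
    state * mean_nascent * intensity_per_rna plus Gaussian noise — the
    active-period level is held at its mean rather than following nascent
    RNA birth-death, a deliberate simplification adequate for validating
    two-level segmentation.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    total_min = p.n_frames * p.dt / 60.0
    p_on = p.k_on / (p.k_on + p.k_off)
    state = int(rng.random() < p_on)

    # event-driven switching; the final event is kept unclipped (beyond the
    # recording end) so every inter-event interval is a full exponential draw
    switch_times = [0.0]
    t = 0.0
    s = state
    while t < total_min:
        rate = p.k_off if s == 1 else p.k_on
        t += rng.exponential(1.0 / rate)
        switch_times.append(t)
        s = 1 - s
    switch_times = np.asarray(switch_times)

    mid = (np.arange(p.n_frames) + 0.5) * p.dt / 60.0
    # state at each midpoint: index of the dwell interval containing it
    idx = np.searchsorted(switch_times, mid, side="right") - 1
    frame_states = (state + idx) % 2

    level = p.mean_nascent * p.intensity_per_rna
    intensity = frame_states * level + rng.normal(0.0, p.noise_sd, size=p.n_frames)
    return TelegraphTrace(
        intensity=intensity,
        states=frame_states.astype(np.int8),
        switch_times=switch_times,
        initial_state=state,
        params=p,
    )


def simulate_traces(
    n_traces: int,
    params: TelegraphParams,
    population: str | None = None,
) -> tuple[pd.DataFrame, list[TelegraphTrace]]:
    """Simulate ``n_traces`` independent traces into one long-format table.

    Per-trace seeds are spawned from ``params.seed`` so the table is a pure
    function of (spec, seed).
    """
    rows, traces = [], []
    seeds = np.random.SeedSequence(params.seed).spawn(n_traces)
    for i, ss in enumerate(seeds):
        p_i = TelegraphParams(**{**params.__dict__, "seed": ss})
        tr = simulate_telegraph_trace(p_i)
        traces.append(tr)
        rows.append(tr.to_frame(allele_id=i, population=population))
    return pd.concat(rows, ignore_index=True), traces


# ---------------------------------------------------------------------------
# smFISH fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldSpec:
    """Layout of a synthetic two-channel smFISH field.

    Cells are disjoint axis-aligned rectangles tiling the image with an
    elliptical nucleus centered in each; masks follow the label-image
    convention (0 = background, k = cell k).  ``ts_nascent_counts[k]`` is
    the nascent-RNA count at the transcription site of cell k+1 (0 = no TS).
    """

    image_shape: tuple = (512, 512)
    n_cells: int = 9
    psf_sigma: float = 1.3  # px
    # integrated a.u. per mRNA; peak amplitude = I/(2 pi sigma^2) ~ 113,
    # i.e. peak SNR ~ 11 over the default noise_sd, a well-exposed smFISH spot
    single_rna_intensity: float = 1200.0
    ts_nascent_counts: tuple = field(default=None)  # len n_cells
    cyto_spots_per_cell: int = 20
    background: float = 100.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if min(self.single_rna_intensity, self.background) < 0 or self.noise_sd < 0:
            raise ValueError("intensities and noise_sd must be >= 0")
        if self.ts_nascent_counts is None:
            object.__setattr__(self, "ts_nascent_counts", tuple([2] * self.n_cells))
        if len(self.ts_nascent_counts) != self.n_cells:
            raise ValueError(
                f"ts_nascent_counts has length {len(self.ts_nascent_counts)}, expected n_cells={self.n_cells}"
            )


@dataclass
class SmfishField:
    """Rendered field: exon/intron images, label masks and the truth table."""

    exon: np.ndarray
    intron: np.ndarray
    nucleus_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    truth: pd.DataFrame
    spec: FieldSpec


def _render_spots(shape, xs, ys, intensities, sigma, rng_noise, background, noise_sd):
    img = np.full(shape, float(background))
    half = int(np.ceil(4 * sigma))
    for x, y, inten in zip(xs, ys, intensities):
        r0, r1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
        c0, c1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
        r0c, r1c = max(r0, 0), min(r1, shape[0])
        c0c, c1c = max(c0, 0), min(c1, shape[1])
        rr = np.arange(r0c, r1c)[:, None]
        cc = np.arange(c0c, c1c)[None, :]
        amp = inten / (2 * np.pi * sigma**2)
        img[r0c:r1c, c0c:c1c] += amp * np.exp(
            -((rr - x) ** 2 + (cc - y) ** 2) / (2 * sigma**2)
        )
    if noise_sd > 0:
        img += rng_noise.normal(0.0, noise_sd, size=shape)
    return np.clip(img, 0, None)


def _place_points(rng, n, r_lo, r_hi, c_lo, c_hi, min_sep, inside=None, avoid=(), max_tries=2000):
    """Rejection-sample n points separated >= min_sep from each other and from ``avoid``."""
    pts = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries * max(n, 1):
            raise RuntimeError("could not place spots with requested separation")
        x = rng.uniform(r_lo, r_hi)
        y = rng.uniform(c_lo, c_hi)
        if inside is not None and not inside(x, y):
            continue
        if all(
            (x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in list(avoid) + pts
        ):
            pts.append((x, y))
    return pts


def simulate_smfish_field(spec: FieldSpec) -> SmfishField:
    """Render a ground-truthed smFISH field.

    Transcription sites sit inside the nucleus and appear in both channels
    at the same position: exon integrated intensity is
    ``ts_nascent_count * single_rna_intensity`` (and likewise for the
    intron channel, since nascent transcripts retain their introns).
    Cytoplasmic spots are single mRNAs: exon channel only, integrated
    intensity ``single_rna_intensity``.  Spots are kept at least
    ``4 * psf_sigma`` apart so each is resolvable.  The truth table uses the
    downstream spot-table schema (channel, x, y, intensity, cell_id,
    compartment).
    """
    s = spec
    rng = np.random.default_rng(s.seed)
    h, w = s.image_shape

    nuc = np.zeros((h, w), dtype=np.int32)
    cyto = np.zeros((h, w), dtype=np.int32)
    records = []

    if s.n_cells > 0:
        ncols = int(np.ceil(np.sqrt(s.n_cells)))
        nrows = int(np.ceil(s.n_cells / ncols))
        ch, cw = h // nrows, w // ncols
        if min(ch, cw) < 24:
            raise ValueError("image too small for the requested number of cells")
        margin = 3
        for k in range(1, s.n_cells + 1):
            gi, gj = divmod(k - 1, ncols)
            r0, c0 = gi * ch, gj * cw
            r1, c1 = r0 + ch, c0 + cw
            cyto[r0 + margin : r1 - margin, c0 + margin : c1 - margin] = k
            # elliptical nucleus centered in the cell, ~45% of each half-extent
            rc, cc = (r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0
            ra, ca = 0.45 * (ch / 2 - margin), 0.45 * (cw / 2 - margin)
            rr = np.arange(r0, r1)[:, None]
            cols = np.arange(c0, c1)[None, :]
            ell = ((rr - rc) / ra) ** 2 + ((cols - cc) / ca) ** 2 <= 1.0
            nuc[r0:r1, c0:c1][ell] = k

            min_sep = 4 * s.psf_sigma
            ts_count = s.ts_nascent_counts[k - 1]
            inside_nuc = lambda x, y: nuc[int(round(x)), int(round(y))] == k
            inside_cyt = (
                lambda x, y: cyto[int(round(x)), int(round(y))] == k
                and nuc[int(round(x)), int(round(y))] == 0
            )
            ts_pts = (
                _place_points(rng, 1, rc - ra, rc + ra, cc - ca, cc + ca, min_sep, inside_nuc)
                if ts_count > 0
                else []
            )
            cyto_pts = _place_points(
                rng,
                s.cyto_spots_per_cell,
                r0 + margin + 2,
                r1 - margin - 3,
                c0 + margin + 2,
                c1 - margin - 3,
                min_sep,
                inside_cyt,
                avoid=ts_pts,
            )
            for (x, y) in ts_pts:
                inten = ts_count * s.single_rna_intensity
                records.append(("exon", x, y, inten, k, "nuclear", True))
                records.append(("intron", x, y, inten, k, "nuclear", True))
            for (x, y) in cyto_pts:
                records.append(("exon", x, y, s.single_rna_intensity, k, "cytoplasmic", False))

    truth = pd.DataFrame(records, columns=SPOT_COLUMNS + ["is_ts"])
    rng_exon = np.random.default_rng(rng.integers(2**31))
    rng_intron = np.random.default_rng(rng.integers(2**31))

    def channel_img(channel, child):
        sub = truth[truth["channel"] == channel]
        return _render_spots(
            (h, w), sub["x"].to_numpy(), sub["y"].to_numpy(), sub["intensity"].to_numpy(),
            s.psf_sigma, child, s.background, s.noise_sd,
        )

    exon = channel_img("exon", rng_exon)
    intron = channel_img("intron", rng_intron)
    return SmfishField(exon=exon, intron=intron, nucleus_mask=nuc, cytoplasm_mask=cyto, truth=truth, spec=s)


# ---------------------------------------------------------------------------
# population trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectorySpec:
    """Sorted-population relaxation experiment.

    Rates in day^-1.  Each (population, day, replicate) observation is a
    binomial draw of ``n_cells_per_point`` cells at the exact relaxation
    fraction.
    """

    kon: float = 0.052
    koff: float = 0.2385
    a0_by_population: tuple = (("high", 0.45), ("low", 0.06))
    sample_days: tuple = (1.0, 4.0, 6.0, 10.0)
    n_cells_per_point: int = 500
    n_replicates: int = 3
    t0: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kon <= 0 or self.koff <= 0:
            raise ValueError("kon and koff must be positive")
        for pop, a0 in self.a0_by_population:
            if not 0.0 <= a0 <= 1.0:
                raise ValueError(f"a0 for population {pop!r} must be in [0, 1]")
        days = np.asarray(self.sample_days, dtype=float)
        if np.any(days < 0) or np.any(np.diff(days) <= 0):
            raise ValueError("sample_days must be non-negative and strictly increasing")


def simulate_population_trajectories(spec: TrajectorySpec) -> pd.DataFrame:
    """Simulate fraction-transcribing tables for each sorted population.

    The exact fraction at each day comes from the relaxation solution with
    lambda = kon + koff and A_eq = kon/(kon + koff); the observed fraction
    per replicate is Binomial(n_cells_per_point, exact) / n_cells_per_point.
    Returns a long table (population, day, fraction_transcribing, n_cells,
    replicate, true_fraction).
    """
    s = spec
    rng = np.random.default_rng(s.seed)
    aeq = _a_eq(s.kon, s.koff)
    lam = s.kon + s.koff
    rows = []
    for pop, a0 in s.a0_by_population:
        true = _relax(np.asarray(s.sample_days, dtype=float), s.t0, a0, aeq, lam)
        for day, f in zip(s.sample_days, np.atleast_1d(true)):
            for rep in range(s.n_replicates):
                k = rng.binomial(s.n_cells_per_point, f)
                rows.append(
                    {
                        "population": pop,
                        "day": float(day),
                        "fraction_transcribing": k / s.n_cells_per_point,
                        "n_cells": s.n_cells_per_point,
                        "replicate": rep,
                        "true_fraction": float(f),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene universes
# ---------------------------------------------------------------------------


@dataclass
class GeneUniverse:
    universe: list
    set_a: list
    set_b: list


def simulate_gene_universe(
    n_genes: int, n_set_a: int, n_set_b: int, n_overlap: int, seed: int = 0
) -> GeneUniverse:
    """Random gene universe with two sets sharing exactly ``n_overlap`` genes."""
    if n_overlap > min(n_set_a, n_set_b):
        raise ValueError("n_overlap exceeds a set size")
    if max(n_set_a, n_set_b) > n_genes:
        raise ValueError("set size exceeds universe size")
    if n_set_a + n_set_b - n_overlap > n_genes:
        raise ValueError("requested sets cannot fit in the universe")
    rng = np.random.default_rng(seed)
    width = len(str(max(n_genes, 1)))
    universe = [f"GENE{i:0{width}d}" for i in range(n_genes)]
    perm = rng.permutation(n_genes)
    shared = perm[:n_overlap]
    only_a = perm[n_overlap : n_set_a]
    only_b = perm[n_set_a : n_set_a + (n_set_b - n_overlap)]
    set_a = sorted(universe[i] for i in np.concatenate((shared, only_a)).astype(int))
    set_b = sorted(universe[i] for i in np.concatenate((shared, only_b)).astype(int))
    return GeneUniverse(universe=universe, set_a=set_a, set_b=set_b)
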