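"""Synthetic study data with the statistical structure the analysis assumes.

Everything the pipeline consumes can be generated here: stimulus schedules,
per-well motion-index traces, whole plates, frame-stack oracle fixtures for
the MI formula, voltage-clamp current traces, insect diet-assay mortality
tables, and planted-cluster molecular fingerprints.

Phenotype model
---------------
A well's expected MI in a segment is ``baseline x segment_gain`` where the
gain depends on the segment kind (acoustic/tap startle gain, strobe gain,
unity elsewhere).  Vehicle wells freeze under strobing light (strobe gain
well below 1); the hyperactive reference phenotype shows paradoxical strobe
activity (gain above 1).  Dose dependence interpolates between the vehicle
and the full phenotype with a Hill function; concentrations at or above a
toxicity cutoff switch to the lethal profile (near-zero trace).  Noise is
truncated Gaussian, clipped at zero, because MI is a nonnegative sum of
absolute differences.

Determinism: one global integer seed; per-well streams are derived by stable
hashing of (plate, well) so well order never changes results.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .battery import Segment, StimulusSchedule
from .chem_clustering import Fingerprint
from .motion_index import FrameStack, WellTrace
from .pharmacology import EphysTrace

# near-zero activity level used for the lethal profile
_LETHAL_LEVEL = 0.3
_LETHAL_NOISE = 0.2


@dataclass(frozen=True)
class PhenotypeParams:
    """Parameters of one behavioral phenotype class.

    baseline_mi
        Mean resting MI (arbitrary MI units) outside stimulus segments.
    noise_sd
        Scale of the truncated-Gaussian trace noise.
    acoustic_gain
        Multiplicative response during acoustic/tap segments.
    strobe_gain
        Multiplicative activity during strobe segments; below 1 encodes
        freezing (vehicle), above 1 the strobe-driven hyperactivity.
    lethal
        Forces a near-zero trace (battery-average MI below 1).
    ec50_um, hill
        Midpoint and slope of the Hill interpolation between vehicle and
        full phenotype; ``ec50_um=None`` means full effect at any dose.
    toxic_above_um
        Concentration at or above which the lethal profile applies.
    well_cv
        Coefficient of variation of a per-well multiplicative random effect
        on the activity level (well-to-well biological variability of the
        8-larva ensemble); 0 disables it.
    """

    baseline_mi: float
    noise_sd: float
    acoustic_gain: float = 1.0
    strobe_gain: float = 1.0
    lethal: bool = False
    ec50_um: Optional[float] = None
    hill: float = 2.0
    toxic_above_um: Optional[float] = None
    well_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_mi < 0 or self.noise_sd < 0:
            raise ValueError("baseline_mi and noise_sd must be nonnegative")
        if self.well_cv < 0:
            raise ValueError("well_cv must be nonnegative")
        if self.acoustic_gain < 0 or self.strobe_gain < 0:
            raise ValueError("gains must be nonnegative")
        if self.ec50_um is not None and self.ec50_um <= 0:
            raise ValueError("ec50_um must be positive")


def default_phenotypes() -> dict[str, PhenotypeParams]:
    """Phenotype classes of the reference screen.

    Vehicle larvae freeze under strobing light; the hyperactive reference
    (an endosulfan-like chloride-channel antagonist) is maximally active in a
    sub-micromolar window and lethal at high dose.
    """
    return {
        "vehicle": PhenotypeParams(
            baseline_mi=30.0, noise_sd=6.0, acoustic_gain=3.0, strobe_gain=0.15,
            well_cv=0.15,
        ),
        "lethal_control": PhenotypeParams(
            baseline_mi=0.3, noise_sd=0.2, lethal=True
        ),
        "endosulfan_like": PhenotypeParams(
            baseline_mi=60.0,
            noise_sd=8.0,
            acoustic_gain=3.0,
            strobe_gain=6.0,
            ec50_um=0.2,
            hill=2.0,
            toxic_above_um=12.5,
            well_cv=0.15,
        ),
        "test_inactive": PhenotypeParams(
            baseline_mi=30.0, noise_sd=6.0, acoustic_gain=3.0, strobe_gain=0.15,
            well_cv=0.15,
        ),
        "test_active": PhenotypeParams(
            baseline_mi=55.0,
            noise_sd=8.0,
            acoustic_gain=3.0,
            strobe_gain=5.0,
            ec50_um=2.0,
            hill=2.0,
            toxic_above_um=50.0,
            well_cv=0.15,
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation configuration; the seed fully determines outputs."""

    n_plates: int = 1
    wells_per_plate: int = 96
    larvae_per_well: int = 8
    frame_rate_hz: float = 25.0
    seed: int = 0
    full_battery: bool = True
    n_active_per_plate: int = 3
    phenotypes: dict[str, PhenotypeParams] = field(default_factory=default_phenotypes)

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.wells_per_plate < 1 or self.n_plates < 1:
            raise ValueError("need at least one plate and one well")
        if self.larvae_per_well < 1:
            raise ValueError("need at least one larva per well")


def _well_seed(global_seed: int, plate: str, well: str) -> np.random.SeedSequence:
    """Stable per-well stream: hash plate/well labels, never positions."""
    return np.random.SeedSequence(
        [int(global_seed), zlib.crc32(plate.encode()), zlib.crc32(well.encode())]
    )


# ---------------------------------------------------------------------------
# stimulus battery
# ---------------------------------------------------------------------------

def gen_battery_schedule(config: SimConfig | None = None) -> StimulusSchedule:
    """The default ~20 min behavioral battery.

    Contains acoustic, tap and steady-light assays, one blue and one green
    strobe segment (each 120 s at 4 Hz) and inter-assay rest.  With
    ``config.full_battery=False`` only the two strobe segments (plus rest)
    are scheduled.
    """
    if config is None:
        config = SimConfig()
    blue = dict(wavelength_nm=560.0, irradiance_uw_mm2=18.0, strobe_hz=4.0)
    green = dict(wavelength_nm=525.0, irradiance_uw_mm2=11.0, strobe_hz=4.0)
    if config.full_battery:
        plan = [
            ("rest_acclimate", "rest", 150.0, {}),
            ("acoustic_1", "acoustic", 30.0, {}),
            ("rest_1", "rest", 90.0, {}),
            ("tap_1", "tap", 30.0, {}),
            ("rest_2", "rest", 90.0, {}),
            ("light_steady", "light", 60.0, dict(wavelength_nm=560.0, irradiance_uw_mm2=18.0)),
            ("rest_3", "rest", 90.0, {}),
            ("blue_strobe", "strobe", 120.0, blue),
            ("rest_4", "rest", 120.0, {}),
            ("green_strobe", "strobe", 120.0, green),
            ("rest_final", "rest", 300.0, {}),
        ]
    else:
        plan = [
            ("rest_acclimate", "rest", 60.0, {}),
            ("blue_strobe", "strobe", 120.0, blue),
            ("rest_4", "rest", 60.0, {}),
            ("green_strobe", "strobe", 120.0, green),
            ("rest_final", "rest", 60.0, {}),
        ]
    t = 0.0
    segments = []
    for label, kind, dur, extra in plan:
        if dur <= 0:
            raise ValueError(f"segment {label!r} has zero duration")
        segments.append(Segment(label=label, kind=kind, start_s=t, end_s=t + dur, **extra))
        t += dur
    return StimulusSchedule(tuple(segments))


_KIND_TO_GAIN = {"acoustic": "acoustic_gain", "tap": "acoustic_gain", "strobe": "strobe_gain"}


def _segment_level(params: PhenotypeParams, segment: Segment) -> float:
    attr = _KIND_TO_GAIN.get(segment.kind)
    gain = getattr(params, attr) if attr else 1.0
    return params.baseline_mi * gain


def _hill_fraction(conc: float, ec50: float, hill: float) -> float:
    return conc**hill / (conc**hill + ec50**hill)


# ---------------------------------------------------------------------------
# well traces and plates
# ---------------------------------------------------------------------------

def gen_well_trace(
    schedule: StimulusSchedule,
    params: PhenotypeParams,
    concentration_um: Optional[float] = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    frame_rate_hz: float = 25.0,
    vehicle: Optional[PhenotypeParams] = None,
    plate: str = "",
    well: str = "",
    treatment: str = "",
) -> WellTrace:
    """Simulate one well's MI trace over a battery.

    The expected MI in each segment is the dose-interpolated phenotype level
    (vehicle level at zero effect, ``baseline x gain`` at full effect);
    truncated Gaussian noise is added and the trace clipped at zero.
    """
    if concentration_um is not None and concentration_um < 0:
        raise ValueError("concentration must be nonnegative")
    n = int(round(schedule.total_s * frame_rate_hz))
    if n < 1:
        raise ValueError("schedule too short for the frame rate")

    lethal = params.lethal or (
        params.toxic_above_um is not None
        and concentration_um is not None
        and concentration_um >= params.toxic_above_um
    )
    rng = np.random.default_rng(seed)
    times = (np.arange(n) + 1) / frame_rate_hz
    if lethal:
        level = np.full(n, _LETHAL_LEVEL)
        noise = min(params.noise_sd, _LETHAL_NOISE)
    else:
        # per-well biological random effect (drawn first: stream stability)
        well_scale = max(0.1, 1.0 + rng.standard_normal() * params.well_cv)
        if params.ec50_um is None or concentration_um is None:
            f = 1.0
        else:
            f = _hill_fraction(concentration_um, params.ec50_um, params.hill)
        level = np.empty(n)
        for seg in schedule:
            mask = (times > seg.start_s) & (times <= seg.end_s)
            full = _segment_level(params, seg)
            if vehicle is not None:
                base = _segment_level(vehicle, seg)
            else:
                base = params.baseline_mi  # zero-effect limit: unit gains
            level[mask] = (1.0 - f) * base + f * full
        level *= well_scale
        if vehicle is not None:
            noise = (1.0 - f) * vehicle.noise_sd + f * params.noise_sd
        else:
            noise = params.noise_sd
    mi = level + rng.normal(0.0, 1.0, size=n) * noise if noise > 0 else level.copy()
    np.clip(mi, 0.0, None, out=mi)
    return WellTrace(
        plate=plate,
        well=well,
        treatment=treatment,
        concentration_um=concentration_um,
        mi=mi,
        frame_rate_hz=frame_rate_hz,
    )


def default_plate_map(config: SimConfig, plate_index: int = 0) -> pd.DataFrame:
    """96-well layout: column 1 vehicle, column 2 controls, the rest test wells.

    Column 2 rows A-D carry the lethal control, rows E-H the hyperactive
    reference at its optimal dose.  ``n_active_per_plate`` of the test wells
    (deterministically, from the plate's hash stream) carry a planted active
    phenotype; the rest are inactive test compounds at 10 uM.
    """
    plate = f"P{plate_index + 1:03d}"
    rows = "ABCDEFGH"
    wells = [f"{r}{c}" for c in range(1, 13) for r in rows][: config.wells_per_plate]
    rng = np.random.default_rng(_well_seed(config.seed, plate, "__layout__"))
    records = []
    test_idx = 0
    test_well_names = []
    for w in wells:
        col = int(w[1:])
        if col == 1:
            records.append((plate, w, "vehicle", "vehicle", None))
        elif col == 2:
            if w[0] in "ABCD":
                records.append((plate, w, "lethal_control", "lethal_control", None))
            else:
                records.append((plate, w, "endosulfan_like", "endosulfan_like", 0.39))
        else:
            test_idx += 1
            cid = f"test_{plate}_{test_idx:03d}"
            records.append((plate, w, "test_inactive", cid, 10.0))
            test_well_names.append(len(records) - 1)
    n_active = min(config.n_active_per_plate, len(test_well_names))
    if n_active:
        chosen = rng.choice(len(test_well_names), size=n_active, replace=False)
        for i in sorted(chosen):
            idx = test_well_names[i]
            p, w, _, cid, conc = records[idx]
            records[idx] = (p, w, "test_active", cid, conc)
    return pd.DataFrame(
        records, columns=["plate", "well", "role", "treatment", "concentration_um"]
    )


def gen_plate(
    config: SimConfig,
    plate_index: int = 0,
    plate_map: Optional[pd.DataFrame] = None,
) -> tuple[list[WellTrace], pd.DataFrame]:
    """Simulate every well of one plate against the battery schedule.

    Every plate must carry vehicle wells: they are the solvent null for hit
    calling and the anchor of the dose interpolation.
    """
    if plate_map is None:
        plate_map = default_plate_map(config, plate_index)
    required = {"plate", "well", "role", "treatment", "concentration_um"}
    if not required.issubset(plate_map.columns):
        raise ValueError(f"plate map must have columns {sorted(required)}")
    if not (plate_map["role"] == "vehicle").any():
        raise ValueError("plate map has no vehicle wells")
    unknown = set(plate_map["role"]) - set(config.phenotypes)
    if unknown:
        raise ValueError(f"roles without phenotype parameters: {sorted(unknown)}")
    schedule = gen_battery_schedule(config)
    vehicle = config.phenotypes["vehicle"]
    traces = []
    for rec in plate_map.itertuples(index=False):
        params = config.phenotypes[rec.role]
        conc = None if pd.isna(rec.concentration_um) else float(rec.concentration_um)
        traces.append(
            gen_well_trace(
                schedule,
                params,
                conc,
                seed=_well_seed(config.seed, rec.plate, rec.well),
                frame_rate_hz=config.frame_rate_hz,
                vehicle=None if rec.role == "vehicle" else vehicle,
                plate=rec.plate,
                well=rec.well,
                treatment=rec.treatment,
            )
        )
    return traces, plate_map


def gen_screen(config: SimConfig) -> tuple[list[WellTrace], pd.DataFrame]:
    """All plates of a screening run; one trace per well, maps concatenated."""
    traces: list[WellTrace] = []
    maps = []
    for p in range(config.n_plates):
        t, m = gen_plate(config, p)
        traces.extend(t)
        maps.append(m)
    return traces, pd.concat(maps, ignore_index=True)


# ---------------------------------------------------------------------------
# frame-stack oracle fixtures
# ---------------------------------------------------------------------------

def gen_frames(
    target: Sequence[int],
    *,
    shape: tuple[int, int] = (16, 16),
    dtype: np.dtype = np.uint16,
    frame_rate_hz: float = 25.0,
    well: str = "A1",
) -> FrameStack:
    """Frame stack whose per-step MI inside the well ROI equals ``target`` exactly.

    Constructed by moving a round-robin set of pixels up or down by known
    amounts: each step's total absolute change is the target value.  Per-pixel
    moves are capped at half the dtype maximum so a move is always feasible in
    one direction; a target step larger than ``half_max x n_pixels`` is not
    representable at this geometry and is rejected.
    """
    tv = np.asarray(target)
    if tv.ndim != 1:
        raise ValueError("target must be a 1-D sequence")
    if tv.size and (np.any(tv < 0) or np.any(tv != np.floor(tv))):
        raise ValueError("target values must be nonnegative integers")
    tv = tv.astype(np.int64)
    info = np.iinfo(dtype)
    half = info.max // 2
    h, w = shape
    npix = h * w
    frames = np.zeros((tv.size + 1, h, w), dtype=np.int64)
    cur = np.zeros(npix, dtype=np.int64)
    ptr = 0
    for t, v in enumerate(tv):
        if v > half * npix:
            raise ValueError(
                f"target step {int(v)} not representable with {npix} pixels "
                f"at bit depth {info.bits}"
            )
        rem = int(v)
        k = 0
        while rem > 0:
            j = (ptr + k) % npix
            k += 1
            s = min(rem, half)
            if cur[j] >= s:
                cur[j] -= s
            else:
                cur[j] += s
            rem -= s
        ptr = (ptr + k) % npix
        frames[t + 1] = cur.reshape(h, w)
    return FrameStack(
        frames=frames.astype(dtype),
        frame_rate_hz=frame_rate_hz,
        rois={well: (0, 0, h, w)},
    )


# ---------------------------------------------------------------------------
# voltage-clamp traces
# ---------------------------------------------------------------------------

def gen_ephys_trace(
    i_gaba_na: float = 400.0,
    rundown_frac: float = 0.1,
    block_frac: float = 0.5,
    noise_sd: float = 2.0,
    seed: int | np.random.SeedSequence = 0,
    *,
    sampling_hz: float = 50.0,
    leak_na: float = -30.0,
    epoch_s: float = 20.0,
    onset_tau_s: float = 0.5,
    oocyte_id: str = "oocyte",
    treatment: str = "compound",
) -> EphysTrace:
    """Annotated clamp-current trace: baseline, GABA, co-application, washout.

    Inward currents are negative.  Desensitization rundown is applied once at
    entry into the co-application epoch and persists into the washout, so an
    untreated control trace (``block_frac=0``) exhibits exactly
    ``1 - post/pre = rundown_frac`` — the quantity the rundown estimator
    measures on control oocytes.  The co-application steady amplitude is
    ``i_gaba x (1 - rundown) x (1 - block)`` plus noise.
    """
    if not 0.0 <= block_frac <= 1.0:
        raise ValueError("block_frac must be in [0, 1]")
    if not 0.0 <= rundown_frac < 1.0:
        raise ValueError("rundown_frac must be in [0, 1)")
    if i_gaba_na <= 0:
        raise ValueError("i_gaba_na must be positive")
    if epoch_s < 2.0:
        raise ValueError("epochs must be at least 2 s for steady-state measurement")
    labels = ["baseline", "gaba_only_pre", "coapplication", "gaba_only_post"]
    amps = {
        "baseline": 0.0,
        "gaba_only_pre": i_gaba_na,
        "coapplication": i_gaba_na * (1.0 - rundown_frac) * (1.0 - block_frac),
        "gaba_only_post": i_gaba_na * (1.0 - rundown_frac),
    }
    n_per = int(round(epoch_s * sampling_hz))
    epochs = {}
    current = np.full(n_per * len(labels), leak_na)
    for k, lab in enumerate(labels):
        t0, t1 = k * epoch_s, (k + 1) * epoch_s
        epochs[lab] = (t0, t1)
        if amps[lab] > 0:
            t_local = np.arange(n_per) / sampling_hz
            onset = 1.0 - np.exp(-t_local / onset_tau_s) if onset_tau_s > 0 else 1.0
            current[k * n_per : (k + 1) * n_per] -= amps[lab] * onset
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, size=current.size)
    time_s = np.arange(current.size) / sampling_hz
    return EphysTrace(
        time_s=time_s,
        current_na=current,
        sampling_hz=sampling_hz,
        epochs=epochs,
        oocyte_id=oocyte_id,
        treatment=treatment,
    )


# ---------------------------------------------------------------------------
# insect diet-assay mortality
# ---------------------------------------------------------------------------

def loglogistic_mortality(dose: np.ndarray | float, lc50: float, slope: float) -> np.ndarray | float:
    """Two-parameter log-logistic death probability with asymptotes 0 and 1."""
    dose = np.asarray(dose, dtype=float)
    return 1.0 / (1.0 + (dose / lc50) ** (-slope))


def gen_mortality(
    doses: Sequence[float],
    lc50: float,
    slope: float,
    n_reps: int = 12,
    larvae_per_well: tuple[int, int] = (3, 5),
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Diet-assay mortality table: per-larva Bernoulli deaths, well outcome
    by the least-affected-individual rule (a well is dead only if every larva is).

    ``lc50=inf`` is the zero-potency limit (all larvae survive).
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0 or np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if not lc50 > 0:
        raise ValueError("lc50 must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    lo, hi = larvae_per_well
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        p = float(loglogistic_mortality(d, lc50, slope)) if np.isfinite(lc50) else 0.0
        for r in range(n_reps):
            n_larvae = int(rng.integers(lo, hi + 1))
            n_dead = int(rng.binomial(n_larvae, p))
            rows.append(
                {
                    "dose_ug_per_well": d,
                    "well_id": f"d{d:g}_r{r + 1:02d}",
                    "replicate": r + 1,
                    "n_larvae": n_larvae,
                    "n_dead": n_dead,
                    "well_dead": n_dead == n_larvae,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planted-cluster fingerprints
# ---------------------------------------------------------------------------

def gen_fingerprints(
    n_clusters: int,
    n_per_cluster: int | Sequence[int],
    n_bits: int = 2048,
    within_sim: float = 0.6,
    n_on: int = 32,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[Fingerprint], list[int]]:
    """Planted-cluster binary fingerprints for clustering tests.

    Members of a cluster share a core bit set sized so the pairwise Tanimoto
    within a cluster is at least ``within_sim``; clusters use disjoint bit
    ranges so between-cluster similarity is exactly 0 (well below any
    operating threshold).  Bit positions are permuted by the seeded stream.

    Returns the fingerprints and their planted cluster labels.
    """
    if not 0.0 < within_sim <= 1.0:
        raise ValueError("within_sim must be in (0, 1]")
    if n_clusters < 1 or n_on < 1:
        raise ValueError("need at least one cluster and one on-bit")
    sizes = (
        [int(n_per_cluster)] * n_clusters
        if np.isscalar(n_per_cluster)
        else list(n_per_cluster)
    )
    if len(sizes) != n_clusters or min(sizes) < 1:
        raise ValueError("cluster sizes must be positive, one per cluster")
    # shared core size: Tanimoto between two members = core / (2*n_on - core)
    core = int(np.ceil(2 * n_on * within_sim / (1.0 + within_sim)))
    core = min(max(core, 1), n_on)
    private = n_on - core
    total_bits = sum(core + m * private for m in sizes)
    if total_bits > n_bits:
        raise ValueError(
            f"infeasible similarity target: construction needs {total_bits} bits, "
            f"only {n_bits} available"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_bits)
    fps: list[Fingerprint] = []
    labels: list[int] = []
    pos = 0
    for k, m in enumerate(sizes):
        core_bits = perm[pos : pos + core]
        pos += core
        for j in range(m):
            priv = perm[pos : pos + private]
            pos += private
            bits = np.zeros(n_bits, dtype=bool)
            bits[core_bits] = True
            bits[priv] = True
            fps.append(
                Fingerprint(
                    compound_id=f"c{k + 1:02d}_m{j + 1:02d}",
                    bits=bits,
                    params={"generator": "planted", "within_sim": within_sim},
                )
            )
            labels.append(k)
    return fps, labels
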