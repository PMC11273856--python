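"""End-to-end study orchestration: per-subject processing and the cohort
statistics battery, plus the synthetic-cohort experiment driver.

Per subject the processing order follows the acquisition-analysis chain:
the stress volume is rigidly registered to the baseline volume (transform
estimated on enhanced copies, applied to the raw volume) and resampled onto
the baseline grid; both volumes are then enhanced (diffusion + adaptive
compensation) and segmented; morphometry is measured on both using the fovea
located on the baseline volume, so the paired endpoints compare the same
retinal location.  HRV metrics are computed from the 20 s RR window preceding
each acquisition's end.  When two baseline scans exist the second is the
analysis baseline and the pair feeds Bland-Altman repeatability; a baseline
scan failing segmentation QC is substituted by the alternate scan when
present, otherwise the subject is excluded with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enhancement import CompensationParams, DiffusionParams, enhance_volume
from .hrv import HRVMetrics, RRSeries, session_metrics
from .morphometry import Calibration, FoveaLocation, MorphometryResult, locate_fovea, measure_volume
from .registration import estimate_rigid, half_transforms, resample_to_grid
from .segmentation import SegmentationParams, SurfaceSet, segment_volume
from .statistics import BlandAltmanResult, PairedComparison, bland_altman, correlate, paired_compare
from .synthetic_data import (
    EyeGeometryConfig,
    NoiseConfig,
    StressEffectConfig,
    apply_stress_effect,
    generate_eye,
    generate_stress_session_rr,
    render_volume,
)
from .volume import OCTVolume

__all__ = [
    "PipelineConfig",
    "SubjectManifest",
    "SubjectResult",
    "StudyReport",
    "analyze_pair",
    "run_subject",
    "run_cohort",
    "simulate_subject",
    "simulate_cohort",
]

THICKNESS_PARAMS = ("RT_1mm", "RT_3mm", "CT_1mm", "CT_3mm")
RADIUS_PARAMS = ("R_0", "R_45", "R_90", "R_135")


@dataclass
class PipelineConfig:
    """Tunables of the per-subject chain; defaults are the analysis defaults."""

    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    compensation: CompensationParams = field(default_factory=CompensationParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    register: bool = True
    hrv_window_s: float = 20.0
    alpha: float = 0.05


@dataclass
class SubjectManifest:
    """Paths and metadata for one subject's session files."""

    subject_id: str
    axial_length_mm: float
    baseline_paths: list[str]
    stress_path: str
    rr_path: str | None = None
    events_path: str | None = None
    baseline_event: str = "baseline_end"
    stress_event: str = "stress_end"
    orientation: str = "left"

    def __post_init__(self) -> None:
        if not (15.0 <= self.axial_length_mm <= 40.0):
            raise ValueError("axial length implausible (expect 15-40 mm)")
        if not self.baseline_paths:
            raise ValueError("at least one baseline volume required")


@dataclass
class SubjectResult:
    """Everything measured for one subject."""

    subject_id: str
    axial_length_mm: float
    baseline: MorphometryResult
    stress: MorphometryResult
    baseline_repeat: MorphometryResult | None = None
    baseline_unresampled: MorphometryResult | None = None
    hrv_baseline: HRVMetrics | None = None
    hrv_stress: HRVMetrics | None = None
    fovea: FoveaLocation | None = None
    qc_flags: list[str] = field(default_factory=list)
    truth: dict = field(default_factory=dict)


@dataclass
class StudyReport:
    """Cohort-level output: paired comparisons, repeatability, correlations."""

    comparisons: dict[str, PairedComparison]
    bland_altman: dict[str, BlandAltmanResult]
    correlations: dict[str, object]
    n_processed: int
    n_excluded: int
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def summary_rows(self) -> list[dict]:
        rows = []
        for name, c in self.comparisons.items():
            rows.append(
                {
                    "parameter": name,
                    "baseline_mean": float(np.mean(c.baseline)),
                    "baseline_sd": float(np.std(c.baseline, ddof=1)),
                    "condition_mean": float(np.mean(c.condition)),
                    "condition_sd": float(np.std(c.condition, ddof=1)),
                    "diff_mean": c.mean_difference,
                    "diff_sd": c.sd_difference,
                    "test": c.test_used,
                    "p": c.p_value,
                }
            )
        return rows


def _segment_checked(
    vol: OCTVolume, config: PipelineConfig
) -> tuple[SurfaceSet, bool]:
    enhanced = enhance_volume(vol, config.diffusion, config.compensation)
    surfaces = segment_volume(enhanced, config.segmentation)
    return surfaces, bool(surfaces.meta.get("poor_quality", False))


def analyze_pair(
    baseline: OCTVolume,
    stress: OCTVolume,
    config: PipelineConfig | None = None,
    baseline_alternate: OCTVolume | None = None,
) -> SubjectResult:
    """Process one baseline/stress volume pair (optionally with the alternate
    baseline scan for repeatability and QC substitution)."""
    config = config or PipelineConfig()
    qc: list[str] = []

    surf_base, poor = _segment_checked(baseline, config)
    if poor and baseline_alternate is not None:
        qc.append("baseline scan substituted by alternate (poor segmentation quality)")
        baseline, baseline_alternate = baseline_alternate, None
        surf_base, poor = _segment_checked(baseline, config)
    if poor:
        raise RuntimeError("baseline segmentation poor quality and no alternate scan")

    if config.register:
        enh_base = enhance_volume(baseline, config.diffusion, config.compensation)
        enh_stress = enhance_volume(stress, config.diffusion, config.compensation)
        reg = estimate_rigid(enh_stress, enh_base)
        if reg.status != "converged":
            qc.append("registration fell back to identity")
        # symmetric resampling: both sessions go through one interpolation
        # pass (half the motion each) onto a common mid-space grid, so
        # resampling smoothing cancels in the paired thickness differences
        s_half, s_half_inv = half_transforms(reg.transform)
        base_pair = resample_to_grid(baseline, s_half_inv, baseline)
        stress_pair = resample_to_grid(stress, s_half, baseline)
        surf_base_pair, _ = _segment_checked(base_pair, config)
    else:
        base_pair = baseline
        stress_pair = stress
        surf_base_pair = surf_base

    surf_stress, poor_stress = _segment_checked(stress_pair, config)
    if poor_stress:
        qc.append("stress segmentation flagged poor quality")

    cal = Calibration.from_volume(baseline)
    fovea = locate_fovea(surf_base_pair)
    res_base = measure_volume(surf_base_pair, cal, fovea, baseline.orientation)
    res_stress = measure_volume(surf_stress, cal, fovea, baseline.orientation)

    # within-session repeatability compares the two raw baseline scans with
    # identical (resampling-free) processing
    res_repeat = None
    res_base_raw = None
    if baseline_alternate is not None:
        surf_rep, poor_rep = _segment_checked(baseline_alternate, config)
        if poor_rep:
            qc.append("repeat baseline scan flagged poor quality; excluded from repeatability")
        else:
            res_repeat = measure_volume(surf_rep, cal, locate_fovea(surf_rep), baseline.orientation)
            res_base_raw = measure_volume(surf_base, cal, locate_fovea(surf_base), baseline.orientation)

    return SubjectResult(
        subject_id="",
        axial_length_mm=baseline.axial_length_mm,
        baseline=res_base,
        stress=res_stress,
        baseline_repeat=res_repeat,
        baseline_unresampled=res_base_raw,
        fovea=fovea,
        qc_flags=qc,
    )


def run_subject(manifest: SubjectManifest, config: PipelineConfig | None = None) -> SubjectResult:
    """Load a subject's files and run the full per-subject analysis."""
    from .hrv import load_rr_export
    from .volume import load_volume

    config = config or PipelineConfig()
    vols = [
        load_volume(p, axial_length_mm=manifest.axial_length_mm, orientation=manifest.orientation)
        for p in manifest.baseline_paths
    ]
    stress = load_volume(
        manifest.stress_path,
        axial_length_mm=manifest.axial_length_mm,
        orientation=manifest.orientation,
    )
    # the second baseline acquisition is the analysis baseline; the first
    # remains for repeatability
    baseline = vols[-1]
    alternate = vols[0] if len(vols) > 1 else None
    result = analyze_pair(baseline, stress, config, baseline_alternate=alternate)
    result.subject_id = manifest.subject_id
    result.axial_length_mm = manifest.axial_length_mm

    if manifest.rr_path is not None:
        rr = load_rr_export(manifest.rr_path, manifest.events_path)
        result.hrv_baseline = session_metrics(
            rr, rr.events[manifest.baseline_event], config.hrv_window_s
        )
        result.hrv_stress = session_metrics(
            rr, rr.events[manifest.stress_event], config.hrv_window_s
        )
    return result


def _endpoint_arrays(results: list[SubjectResult]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for name in THICKNESS_PARAMS + RADIUS_PARAMS:
        b = np.array([r.baseline.as_dict()[name] for r in results])
        c = np.array([r.stress.as_dict()[name] for r in results])
        ok = np.isfinite(b) & np.isfinite(c)  # infinite radii (flat fits) excluded
        out[name] = (b[ok], c[ok])
    return out


def run_cohort(
    results: list[SubjectResult],
    alpha: float = 0.05,
    exclusions: list[tuple[str, str]] | None = None,
) -> StudyReport:
    """The cohort statistics battery over processed subjects.

    Paired comparisons for the eight morphometric endpoints plus HR and
    RMSSD; Bland-Altman repeatability on the baseline scan pairs; and the
    three association analyses (change in CT vs axial length, change in CT vs
    change in HR, baseline RMSSD vs baseline CT).
    """
    if len(results) < 3:
        raise ValueError("need at least 3 processable subjects")
    comparisons: dict[str, PairedComparison] = {}
    for name, (b, c) in _endpoint_arrays(results).items():
        comparisons[name] = paired_compare(b, c, alpha, parameter=name)

    have_hrv = [r for r in results if r.hrv_baseline is not None and r.hrv_stress is not None]
    if len(have_hrv) >= 3:
        hr_b = np.array([r.hrv_baseline.mean_hr_bpm for r in have_hrv])
        hr_c = np.array([r.hrv_stress.mean_hr_bpm for r in have_hrv])
        rm_b = np.array([r.hrv_baseline.rmssd_ms for r in have_hrv])
        rm_c = np.array([r.hrv_stress.rmssd_ms for r in have_hrv])
        comparisons["HR"] = paired_compare(hr_b, hr_c, alpha, parameter="HR")
        comparisons["RMSSD"] = paired_compare(rm_b, rm_c, alpha, parameter="RMSSD")

    ba: dict[str, BlandAltmanResult] = {}
    with_repeat = [r for r in results if r.baseline_repeat is not None]
    if len(with_repeat) >= 2:
        for name in THICKNESS_PARAMS:
            s1 = np.array([r.baseline_repeat.as_dict()[name] for r in with_repeat])
            s2 = np.array(
                [
                    (r.baseline_unresampled or r.baseline).as_dict()[name]
                    for r in with_repeat
                ]
            )
            ba[name] = bland_altman(s1, s2)

    correlations: dict[str, object] = {}

    def _corr(key: str, x: np.ndarray, y: np.ndarray) -> None:
        if x.size >= 4 and np.std(x) > 0 and np.std(y) > 0:
            correlations[key] = correlate(x, y, alpha)

    al = np.array([r.axial_length_mm for r in results])
    for name in ("CT_1mm", "CT_3mm"):
        b, c = _endpoint_arrays(results)[name]
        delta = c - b
        _corr(f"d{name}_vs_axial_length", al, delta)
        if len(have_hrv) >= 4:
            d_hr = np.array(
                [r.hrv_stress.mean_hr_bpm - r.hrv_baseline.mean_hr_bpm for r in have_hrv]
            )
            d_ct = np.array(
                [r.stress.as_dict()[name] - r.baseline.as_dict()[name] for r in have_hrv]
            )
            _corr(f"d{name}_vs_dHR", d_hr, d_ct)
            rm_b = np.array([r.hrv_baseline.rmssd_ms for r in have_hrv])
            ct_b = np.array([r.baseline.as_dict()[name] for r in have_hrv])
            _corr(f"baseline_RMSSD_vs_baseline_{name}", rm_b, ct_b)

    exclusions = exclusions or []
    return StudyReport(
        comparisons=comparisons,
        bland_altman=ba,
        correlations=correlations,
        n_processed=len(results),
        n_excluded=len(exclusions),
        exclusions=exclusions,
    )


# ---------------------------------------------------------------------------
# synthetic-cohort experiment driver


def simulate_subject(
    seed: int,
    geometry: EyeGeometryConfig | None = None,
    delta_ct_um: float | None = None,
    config: PipelineConfig | None = None,
    with_hrv: bool = True,
    with_repeat: bool = True,
) -> SubjectResult:
    """Generate and fully process one synthetic subject.

    Per-subject biology (axial length, layer thicknesses, posterior radius,
    resting heart rate) is drawn around population-scale means; the stress
    effect thickens the choroid by ``delta_ct_um`` (default drawn from
    Normal(3.3, 6.1) um, the cohort effect scale) and adds a small rigid
    between-session motion.
    """
    rng = np.random.default_rng(seed)
    config = config or PipelineConfig()
    if geometry is None:
        geometry = EyeGeometryConfig(
            axial_length_mm=float(np.clip(rng.normal(24.5, 1.0), 22.0, 27.0)),
            retina_thickness_um=(float(np.clip(rng.normal(315.0, 16.0), 260.0, 370.0)), 0.0),
            choroid_thickness_um=(float(np.clip(rng.normal(283.0, 60.0), 150.0, 420.0)), 0.0),
            # a 12 mm field needs R >= ~14.4 mm for the cap to stay in depth
            posterior_radius_mm=float(np.clip(rng.normal(19.0, 4.0), 15.0, 30.0)),
            pit_depth_um=float(np.clip(rng.normal(100.0, 15.0), 60.0, 140.0)),
        )
    if delta_ct_um is None:
        delta_ct_um = float(rng.normal(3.3, 6.1))

    truth = generate_eye(geometry, seed=seed)
    effect = StressEffectConfig(
        delta_ct_um=delta_ct_um,
        rigid_shift_px=(
            float(rng.uniform(-2.0, 2.0)),
            float(rng.uniform(-1.5, 1.5)),
            float(rng.uniform(-1.5, 1.5)),
        ),
        rigid_rot_deg=float(rng.uniform(-1.0, 1.0)),
    )
    truth_stress = apply_stress_effect(truth, effect)

    base1 = render_volume(truth, NoiseConfig(seed=seed * 4 + 1))
    base2 = render_volume(truth, NoiseConfig(seed=seed * 4 + 2))
    stress_vol = render_volume(truth_stress, NoiseConfig(seed=seed * 4 + 3))

    result = analyze_pair(
        base2, stress_vol, config, baseline_alternate=base1 if with_repeat else None
    )
    result.subject_id = f"synthetic-{seed}"
    result.axial_length_mm = geometry.axial_length_mm
    result.truth = {
        "delta_ct_um": delta_ct_um,
        "ct_mean_um": float(np.mean(truth.ct_map_um)),
        "posterior_radius_mm": geometry.posterior_radius_mm,
        "transform": truth_stress.applied_transform,
    }

    if with_hrv:
        base_rr_mean = float(np.clip(rng.normal(779.0, 110.0), 560.0, 1000.0))
        base_rr_sd = float(np.clip(rng.normal(48.0, 14.0), 12.0, base_rr_mean / 3.5))
        stress_rr_mean = float(base_rr_mean * np.clip(rng.normal(0.888, 0.05), 0.72, 0.99))
        stress_rr_sd = float(np.clip(base_rr_sd * rng.normal(0.69, 0.12), 6.0, stress_rr_mean / 3.5))
        rr = generate_stress_session_rr(
            base_rr_mean, base_rr_sd, stress_rr_mean, stress_rr_sd, seed=seed
        )
        result.hrv_baseline = session_metrics(rr, rr.events["baseline_end"], config.hrv_window_s)
        result.hrv_stress = session_metrics(rr, rr.events["stress_end"], config.hrv_window_s)
    return result


def simulate_cohort(
    n_subjects: int = 33,
    seed: int = 0,
    config: PipelineConfig | None = None,
    delta_ct_mean_um: float = 3.3,
    delta_ct_sd_um: float = 6.1,
    with_hrv: bool = True,
    with_repeat: bool = True,
) -> tuple[StudyReport, list[SubjectResult]]:
    """Simulate and analyze a full paired-session cohort.

    Per-subject seeds derive from ``seed``; the choroidal stress effect is
    drawn per subject from Normal(delta_ct_mean_um, delta_ct_sd_um).
    """
    rng = np.random.default_rng(seed)
    results = []
    exclusions: list[tuple[str, str]] = []
    for i in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        delta = float(rng.normal(delta_ct_mean_um, delta_ct_sd_um))
        try:
            results.append(
                simulate_subject(
                    sub_seed,
                    delta_ct_um=delta,
                    config=config,
                    with_hrv=with_hrv,
                    with_repeat=with_repeat,
                )
            )
        except (RuntimeError, ValueError) as exc:  # QC exclusion path
            exclusions.append((f"synthetic-{sub_seed}", str(exc)))
    report = run_cohort(results, exclusions=exclusions)
    return report, results
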