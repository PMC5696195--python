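"""End-to-end orchestration: simulate -> adc -> extract -> change -> analyze -> report.

Every stage is a pure function of its inputs plus the run configuration and
seed; `run_pipeline` chains them, writes all tables under the output
directory, and records a manifest (seed, config hash, library versions) so a
rerun with the same configuration reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adc import AdcMap, compute_adc
from .change import change_rate_table
from .glcm import build_glcm, quantize, texture_features
from .lesion import VoiMask, histogram_features, morphology
from .stats import (
    compare_groups,
    icc_two_observers,
    roc_analysis,
    sidak_adjust,
    stepwise_logistic,
)
from .synthetic import PhantomResult, PhantomSpec, simulate_phantom, two_arm_phantom_specs

__all__ = [
    "FeatureConfig",
    "StatsConfig",
    "CohortConfig",
    "RunConfig",
    "StageError",
    "extract_features",
    "phantom_cohort_features",
    "analyze_cohort",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

MORPH_COLUMNS = ["mtd", "area", "volume"]
HISTOGRAM_COLUMNS = ["adc_mean", "p5", "p10", "p25", "p50", "p75", "p90", "skewness", "kurtosis", "entropy"]
TEXTURE_COLUMNS = ["correlation", "autocorrelation", "entropy_h", "homogeneity"]
FEATURE_COLUMNS = MORPH_COLUMNS + HISTOGRAM_COLUMNS + TEXTURE_COLUMNS


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for error reporting."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class FeatureConfig:
    histogram_bins: int = 128
    kurtosis_convention: str = "pearson"
    glcm_levels: int = 64
    glcm_distance: int = 1
    glcm_normalize: bool = True
    glcm_symmetric: bool = True
    glcm_quantization: str = "equal_width"  # or 'fixed_width'
    glcm_bin_width: float | None = None
    glcm_sigma_dialect: str = "marginal"
    direction_average: str = "features"


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    ci_method: str = "delong"
    p_enter: float = 0.05
    p_remove: float = 0.10
    # family sizes for the Dunn-Sidak correction follow the table layout:
    # per timepoint, 10 histogram features and 4 texture features
    families: tuple[tuple[str, ...], ...] = (tuple(HISTOGRAM_COLUMNS), tuple(TEXTURE_COLUMNS))


@dataclass(frozen=True)
class CohortConfig:
    n_nonrecurrence: int = 8
    n_recurrence: int = 6
    timepoints: tuple[str, ...] = ("pre", "mid")
    #: mid-treatment rise of the solid-compartment ADC per arm (1e-6 mm^2/s),
    #: mirroring the published group-mean ADC increase under therapy
    mid_adc_shift: dict[str, float] = field(
        default_factory=lambda: {"nonrecurrence": 270.0, "recurrence": 190.0}
    )


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "pipeline_out"
    #: optional CSV manifest of real studies (columns: patient_id, timepoint,
    #: outcome, b0, bhigh, mask [, mask_obs2]); when absent, phantoms are simulated
    input_manifest: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "out_dir" in raw:
            kwargs["out_dir"] = str(raw["out_dir"])
        if "input_manifest" in raw:
            kwargs["input_manifest"] = raw["input_manifest"]
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "timepoints" in c:
                c["timepoints"] = tuple(c["timepoints"])
            kwargs["cohort"] = CohortConfig(**c)
        if "features" in raw:
            kwargs["features"] = FeatureConfig(**raw["features"])
        if "stats" in raw:
            s = dict(raw["stats"])
            if "families" in s:
                s["families"] = tuple(tuple(f) for f in s["families"])
            kwargs["stats"] = StatsConfig(**s)
        return cls(**kwargs)


def extract_features(adc_map: AdcMap, voi: VoiMask, cfg: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    """One feature row: 3 morphological + 10 histogram + 4 texture features."""
    morph = morphology(voi)
    hist = histogram_features(
        adc_map, voi, bins=cfg.histogram_bins, kurtosis_convention=cfg.kurtosis_convention
    )
    q = quantize(
        adc_map, voi, G=cfg.glcm_levels, method=cfg.glcm_quantization, bin_width=cfg.glcm_bin_width
    )
    glcms = build_glcm(
        q, distance=cfg.glcm_distance, symmetric=cfg.glcm_symmetric, normalize=cfg.glcm_normalize
    )
    tex = texture_features(
        glcms, sigma_dialect=cfg.glcm_sigma_dialect, direction_average=cfg.direction_average
    )
    row = {"mtd": morph.mtd, "area": morph.area, "volume": morph.volume}
    row.update(hist.as_dict())
    row.update(tex.as_dict())
    return row


def _patient_spec(base: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Patient-level biological variability around an arm's conditions."""
    scale = rng.uniform(0.85, 1.15)
    f = base.necrotic_fraction * rng.uniform(0.8, 1.25)
    return replace(
        base,
        solid_adc_mean=base.solid_adc_mean + rng.normal(0.0, 40.0),
        lesion_axes_mm=tuple(a * scale for a in base.lesion_axes_mm),
        necrotic_fraction=min(f, 0.9),
    )


def simulate_cohort_phantoms(
    cohort: CohortConfig = CohortConfig(),
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> list[dict]:
    """Simulate per-patient, per-timepoint phantoms for a two-arm study.

    Returns one record per (patient, timepoint) with the phantom, outcome
    label and ground truth. The mid-treatment phantom of each patient raises
    the solid-compartment ADC by the arm's treatment effect.
    """
    rng = np.random.default_rng(seed)
    arms = two_arm_phantom_specs(base_spec)
    records: list[dict] = []
    pid = 0
    for outcome, n in (("nonrecurrence", cohort.n_nonrecurrence), ("recurrence", cohort.n_recurrence)):
        for _ in range(n):
            pid += 1
            patient = f"P{pid:03d}"
            spec_pre = _patient_spec(arms[outcome], rng)
            for tp in cohort.timepoints:
                spec = spec_pre
                if tp == "mid":
                    spec = replace(
                        spec_pre,
                        solid_adc_mean=spec_pre.solid_adc_mean + cohort.mid_adc_shift[outcome],
                        lesion_axes_mm=tuple(a * 0.85 for a in spec_pre.lesion_axes_mm),
                    )
                phantom = simulate_phantom(spec, rng)
                records.append(
                    {"patient_id": patient, "timepoint": tp, "outcome": outcome, "phantom": phantom}
                )
    return records


def phantom_cohort_features(
    cohort: CohortConfig = CohortConfig(),
    base_spec: PhantomSpec = PhantomSpec(),
    feature_cfg: FeatureConfig = FeatureConfig(),
    seed: int = 0,
    observers: int = 2,
) -> pd.DataFrame:
    """Simulate a phantom cohort and run the full extraction on it."""
    records = simulate_cohort_phantoms(cohort, base_spec, seed)
    rows = []
    for rec in records:
        phantom: PhantomResult = rec["phantom"]
        adc_map = compute_adc(phantom.study)
        masks = [phantom.mask_obs1, phantom.mask_obs2][:observers]
        for obs, voi in enumerate(masks, start=1):
            row = {
                "patient_id": rec["patient_id"],
                "timepoint": rec["timepoint"],
                "observer": obs,
                "outcome": rec["outcome"],
            }
            row.update(extract_features(adc_map, voi, feature_cfg))
            rows.append(row)
    return pd.DataFrame(rows)


def extract_from_manifest(manifest_path: str | Path, cfg: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Extract features from real NIfTI studies listed in a CSV manifest.

    Required columns: patient_id, timepoint, outcome, b0, bhigh, mask;
    optional mask_obs2 adds a second-observer row. Paths are resolved
    relative to the manifest file. Any missing file raises FileNotFoundError
    (surfaced by ``run_pipeline`` as a failure of the extract stage).
    """
    from .adc import DwiStudy
    from .io import load_mask, load_volume

    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    root = manifest_path.parent
    rows = []
    for _, entry in table.iterrows():
        for col in ("b0", "bhigh", "mask"):
            p = root / str(entry[col])
            if not p.exists():
                raise FileNotFoundError(f"missing {col} volume: {p}")
        b0, geom = load_volume(root / str(entry["b0"]))
        bh, _ = load_volume(root / str(entry["bhigh"]))
        adc_map = compute_adc(DwiStudy(signal_b0=b0, signal_bhigh=bh, geometry=geom))
        mask_cols = [("mask", 1)]
        if "mask_obs2" in table.columns and pd.notna(entry.get("mask_obs2")):
            mask_cols.append(("mask_obs2", 2))
        for col, obs in mask_cols:
            p = root / str(entry[col])
            if not p.exists():
                raise FileNotFoundError(f"missing {col} volume: {p}")
            mask, mgeom = load_mask(p)
            voi = VoiMask(mask=mask, slice_axis=2, geometry=mgeom)
            row = {
                "patient_id": entry["patient_id"],
                "timepoint": entry["timepoint"],
                "observer": obs,
                "outcome": entry.get("outcome", ""),
            }
            row.update(extract_features(adc_map, voi, cfg))
            rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(features: pd.DataFrame, cfg: StatsConfig = StatsConfig()) -> dict:
    """The statistical stage on an extracted feature table.

    Expects columns patient_id / timepoint / observer / outcome plus the 17
    feature columns. Observer 1 is the primary reading; observer 2 (when
    present) feeds the ICC table. Returns comparison + ROC tables per
    timepoint, the Sidak-corrected candidate set, the stepwise model and the
    inter-observer ICC table.
    """
    primary = features[features.get("observer", 1) == 1] if "observer" in features else features
    out: dict = {"comparisons": [], "icc": [], "stepwise": None, "sidak": []}
    candidates: list[tuple[str, str]] = []  # (timepoint, feature) surviving correction

    feature_cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    for tp in sorted(primary["timepoint"].unique()):
        sub = primary[primary["timepoint"] == tp]
        g_non = sub[sub["outcome"] == "nonrecurrence"]
        g_rec = sub[sub["outcome"] == "recurrence"]
        families = [tuple(f for f in fam if f in feature_cols) for fam in cfg.families]
        fam_alpha = {
            feat: sidak_adjust(cfg.alpha, len(fam)) for fam in families if fam for feat in fam
        }
        for feat in feature_cols:
            comp = compare_groups(g_non[feat], g_rec[feat], feature=feat)
            roc = roc_analysis(sub[feat].to_numpy(), (sub["outcome"] == "recurrence").to_numpy(), ci=cfg.ci_method)
            alpha_adj = fam_alpha.get(feat, cfg.alpha)
            survives = comp.p_value < alpha_adj
            out["comparisons"].append(
                {
                    "timepoint": tp,
                    "feature": feat,
                    "test": comp.test,
                    "p_value": comp.p_value,
                    "nonrecurrence_mean": comp.group1.mean,
                    "nonrecurrence_sd": comp.group1.sd,
                    "recurrence_mean": comp.group2.mean,
                    "recurrence_sd": comp.group2.sd,
                    "nonrecurrence_median": comp.group1.median,
                    "recurrence_median": comp.group2.median,
                    "auc": roc.auc,
                    "auc_ci_low": roc.auc_ci_low,
                    "auc_ci_high": roc.auc_ci_high,
                    "cutoff": roc.cutoff,
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                    "accuracy": roc.accuracy,
                    "positive_on_low": roc.positive_on_low,
                    "sidak_alpha": alpha_adj,
                    "significant_after_sidak": bool(survives),
                }
            )
            if survives and feat not in MORPH_COLUMNS:
                candidates.append((tp, feat))

        if "observer" in features.columns and set(features["observer"].unique()) >= {1, 2}:
            sub_all = features[features["timepoint"] == tp]
            o1 = sub_all[sub_all["observer"] == 1].set_index("patient_id")
            o2 = sub_all[sub_all["observer"] == 2].set_index("patient_id")
            common = o1.index.intersection(o2.index)
            for feat in feature_cols:
                if feat in MORPH_COLUMNS:
                    continue
                icc = icc_two_observers(o1.loc[common, feat], o2.loc[common, feat])
                out["icc"].append(
                    {"timepoint": tp, "feature": feat, "icc": icc.icc, "ci_low": icc.ci_low, "ci_high": icc.ci_high}
                )

    if len(candidates) >= 2:
        wide = primary.pivot_table(index="patient_id", columns="timepoint", values=feature_cols, aggfunc="first")
        cols = {}
        for tp, feat in candidates:
            col = f"{tp}_{feat}"
            cols[col] = wide[(feat, tp)]
        X = pd.DataFrame(cols).dropna()
        labels = (
            primary.drop_duplicates("patient_id").set_index("patient_id").loc[X.index, "outcome"]
            == "recurrence"
        ).to_numpy()
        if X.shape[1] >= 2 and labels.any() and not labels.all():
            sw = stepwise_logistic(X, labels, p_enter=cfg.p_enter, p_remove=cfg.p_remove)
            out["stepwise"] = {
                "selected": sw.selected,
                "wald_p": sw.wald_p,
                "coef": sw.coef,
                "separation": sw.separation,
            }
    out["sidak"] = [{"timepoint": tp, "feature": f} for tp, f in candidates]
    return out


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full synthetic study and write every table under out_dir.

    Emits features.csv (per patient/timepoint/observer), change_rates.csv,
    comparisons.csv (the group-comparison + ROC table), icc.csv,
    stepwise.json and manifest.json. Raises :class:`StageError` naming the
    failing stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if config.input_manifest is not None:
        try:
            features = extract_from_manifest(config.input_manifest, config.features)
        except Exception as e:  # noqa: BLE001
            raise StageError("extract", e) from e
    else:
        try:
            features = phantom_cohort_features(
                cohort=config.cohort, feature_cfg=config.features, seed=config.seed
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("simulate/extract", e) from e
    logger.info("extracted %d feature rows", len(features))
    paths["features"] = out_dir / "features.csv"
    features.to_csv(paths["features"], index=False)

    try:
        primary = features[features["observer"] == 1]
        changes = change_rate_table(
            primary.drop(columns=["observer", "outcome"]),
            feature_columns=[c for c in FEATURE_COLUMNS if c in features.columns],
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("change", e) from e
    paths["change_rates"] = out_dir / "change_rates.csv"
    changes.to_csv(paths["change_rates"], index=False)

    try:
        analysis = analyze_cohort(features, config.stats)
    except Exception as e:  # noqa: BLE001
        raise StageError("analyze", e) from e

    paths["comparisons"] = out_dir / "comparisons.csv"
    pd.DataFrame(analysis["comparisons"]).to_csv(paths["comparisons"], index=False)
    paths["icc"] = out_dir / "icc.csv"
    pd.DataFrame(analysis["icc"]).to_csv(paths["icc"], index=False)
    paths["stepwise"] = out_dir / "stepwise.json"
    paths["stepwise"].write_text(json.dumps(analysis["stepwise"], indent=2, sort_keys=True))

    try:
        import scipy

        manifest = {
            "seed": config.seed,
            "config": asdict(config),
            "config_sha256": _config_hash(config),
            "versions": {
                "adcradiomics": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
            },
        }
        paths["manifest"] = out_dir / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    except Exception as e:  # noqa: BLE001
        raise StageError("report", e) from e
    return paths
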