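"""End-to-end robustness runs: inputs → perturbation chains → processing →
features → ICC → classification, with reproducible CSV outputs.

A run takes a cohort of subjects, each with one or two replicate images (two
replicates emulate test-retest acquisition) and an ROI mask.  For every
perturbation chain the full parameter permutation is expanded per subject,
features are computed for each perturbed sample at every configured isotropic
spacing, and each feature's ICC(1,1) + 95% CI over subjects is classified
against the robustness threshold.  With two replicates the perturbation ICC
is averaged over both images and compared against the test-retest ICC.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DegenerateMaskError, RadperturbError
from .features import build_manifest, compute_features
from .image import RoiMask, VolumetricImage, read_image, read_mask
from .perturb import (
    PerturbationChain,
    default_chain_registry,
    estimate_noise_sd,
    expand_chain,
    sample_seed,
)
from .phantom import PhantomSpec, generate_phantom
from .processing import ProcessingConfig, interpolate_to_isotropic, resegment
from .stats import (
    INDETERMINATE,
    MeasurementPanel,
    compare_conditions,
    icc_record,
    perturbation_icc,
)

__all__ = ["RunConfig", "SubjectData", "run_robustness", "validate_config", "make_synthetic_cohort"]


@dataclass
class SubjectData:
    """One subject: 1–2 replicate images with their (shared-geometry) masks."""

    subject_id: str
    images: list[VolumetricImage]
    masks: list[RoiMask]

    def __post_init__(self) -> None:
        if not 1 <= len(self.images) <= 2 or len(self.images) != len(self.masks):
            raise ConfigurationError(
                f"subject {self.subject_id}: need 1 or 2 image+mask replicates"
            )


@dataclass
class RunConfig:
    """Configuration of a robustness run.

    ``subjects`` may be given directly (in-memory), via ``input_manifest``
    (list of dicts with ``subject``, ``images`` (1–2 NIfTI paths) and
    ``masks``), or via ``synthetic`` (dict of :func:`make_synthetic_cohort`
    keyword arguments) — exactly one source.
    """

    chains: list[str] = field(default_factory=lambda: ["N"])
    chain_params: dict = field(default_factory=dict)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    base_seed: int = 0
    alpha: float = 0.05
    threshold: float = 0.90
    out_dir: str | None = None
    export_perturbed: bool = False
    subjects: list[SubjectData] | None = None
    input_manifest: list[dict] | None = None
    synthetic: dict | None = None

    def to_dict(self) -> dict:
        return {
            "chains": list(self.chains),
            "chain_params": self.chain_params,
            "processing": self.processing.to_dict(),
            "base_seed": self.base_seed,
            "alpha": self.alpha,
            "threshold": self.threshold,
            "out_dir": self.out_dir,
            "export_perturbed": self.export_perturbed,
            "input_manifest": self.input_manifest,
            "synthetic": self.synthetic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "processing" in d and isinstance(d["processing"], dict):
            d["processing"] = ProcessingConfig.from_dict(d["processing"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_synthetic_cohort(
    n_subjects: int = 10,
    replicates: int = 2,
    seed: int = 0,
    shape: tuple[int, int, int] = (36, 36, 36),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    radius_range: tuple[float, float] = (8.0, 14.0),
    foreground_range: tuple[float, float] = (20.0, 80.0),
    texture_range_range: tuple[float, float] = (30.0, 90.0),
    noise_sd: float = 10.0,
    texture: str = "random",
) -> list[SubjectData]:
    """Generate a synthetic test-retest cohort of textured phantoms.

    Subjects differ in ROI size, intensity level and texture spread
    (between-subject variance — tumour size, density and heterogeneity);
    replicates share geometry and texture but draw independent noise
    realisations, emulating a short-interval re-acquisition.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for s in range(n_subjects):
        radius = float(rng.uniform(*radius_range))
        fg = float(rng.uniform(*foreground_range))
        tex_range = float(rng.uniform(*texture_range_range))
        texture_seed = int(rng.integers(0, 2**31 - 1))
        images, masks = [], []
        for r in range(replicates):
            spec = PhantomSpec(
                shape=shape,
                spacing=spacing,
                radii=(radius, radius * 0.9, radius * 0.8),
                background=-100.0,
                foreground=fg,
                texture=texture,
                texture_range=tex_range,
                noise_sd=noise_sd,
                # same texture across replicates, fresh noise per replicate
                seed=texture_seed,
            )
            img, mask = generate_phantom(spec)
            if noise_sd > 0:
                # replace the spec's noise with a replicate-specific realisation
                base, _ = generate_phantom(
                    PhantomSpec(**{**spec.__dict__, "noise_sd": 0.0})
                )
                noise_rng = np.random.default_rng(
                    sample_seed(seed, f"subject{s}-rep{r}", ())
                )
                img = VolumetricImage(
                    base.voxels + noise_rng.normal(0.0, noise_sd, base.shape),
                    base.spacing,
                    base.origin,
                )
            images.append(img)
            masks.append(mask)
        subjects.append(SubjectData(f"subj{s:03d}", images, masks))
    return subjects


def _load_subjects(config: RunConfig) -> list[SubjectData]:
    sources = [config.subjects, config.input_manifest, config.synthetic]
    if sum(x is not None for x in sources) != 1:
        raise ConfigurationError(
            "exactly one of subjects / input_manifest / synthetic must be set"
        )
    if config.subjects is not None:
        return config.subjects
    if config.synthetic is not None:
        return make_synthetic_cohort(**config.synthetic)
    out = []
    for entry in config.input_manifest:
        images = [read_image(p) for p in entry["images"]]
        masks = [read_mask(p) for p in entry["masks"]]
        out.append(SubjectData(str(entry["subject"]), images, masks))
    return out


def validate_config(config: RunConfig) -> list[str]:
    """Pure validation report: unknown chains, out-of-range parameters,
    missing files.  Out-of-default-range perturbation parameters produce
    warnings, not errors."""
    findings: list[str] = []
    registry = default_chain_registry()
    for label in config.chains:
        if label.upper() not in registry:
            try:
                PerturbationChain.from_label(label, config.chain_params.get(label))
            except Exception as exc:
                findings.append(f"unknown or invalid chain label {label!r}: {exc}")
                continue
        try:
            chain = PerturbationChain.from_label(label, config.chain_params.get(label))
            for spec in chain.specs:
                for msg in spec.validate_ranges():
                    findings.append(f"chain {label}: warning: {msg}")
        except Exception as exc:
            findings.append(f"chain {label}: {exc}")
    if config.input_manifest is not None:
        for entry in config.input_manifest:
            for p in list(entry.get("images", [])) + list(entry.get("masks", [])):
                if not Path(p).exists():
                    findings.append(f"missing file: {p}")
    return findings


@dataclass
class RunResult:
    feature_table: pd.DataFrame
    baseline_table: pd.DataFrame
    icc_tables: dict[str, pd.DataFrame]
    summary: pd.DataFrame
    comparisons: dict[str, pd.DataFrame]
    log: dict


def _features_for_sample(
    image: VolumetricImage,
    mask: RoiMask,
    manifest,
    config: ProcessingConfig,
) -> tuple[dict[str, float], dict[str, str]]:
    morph = mask.copy(kind="morphological")
    imask = resegment(image, morph, config)
    return compute_features(image, morph, imask, manifest, config)


def _icc_table(
    feature_cols: list[str],
    panels: dict[str, np.ndarray],
    alpha: float,
    threshold: float,
    panels2: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    rows = []
    for fid in feature_cols:
        entry = {"feature": fid}
        try:
            if panels2 is None:
                rec = icc_record(MeasurementPanel(panels[fid]), fid, alpha, threshold)
            else:
                rec = perturbation_icc(
                    MeasurementPanel(panels[fid]),
                    MeasurementPanel(panels2[fid]),
                    fid, alpha, threshold,
                )
            entry.update(
                icc=rec.estimate, ci_lower=rec.lower, ci_upper=rec.upper,
                n=rec.n, k=rec.k, msb=rec.msb, msw=rec.msw,
                label=rec.label, undefined=rec.undefined,
            )
        except (RadperturbError, KeyError) as exc:
            entry.update(
                icc=np.nan, ci_lower=np.nan, ci_upper=np.nan, n=0, k=0,
                msb=np.nan, msw=np.nan, label=INDETERMINATE, undefined=True,
            )
        rows.append(entry)
    return pd.DataFrame(rows).set_index("feature")


def _panel(df: pd.DataFrame, fid: str) -> np.ndarray | None:
    """Subjects × samples matrix for one feature; listwise NaN drop."""
    wide = df.pivot_table(index="subject", columns="sample", values=fid, dropna=False)
    wide = wide.dropna(axis=0, how="any")
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        return None
    return wide.to_numpy()


def run_robustness(config: RunConfig) -> RunResult:
    """Execute a full robustness run; writes CSVs when ``out_dir`` is set."""
    t0 = time.time()
    subjects = _load_subjects(config)
    if len(subjects) < 2:
        raise ConfigurationError("a robustness run needs at least 2 subjects")
    if not config.chains:
        raise ConfigurationError("a robustness run needs at least 1 chain")
    proc = config.processing
    manifest = build_manifest(proc)
    feature_cols = manifest.full_ids()
    n_replicates = min(len(s.images) for s in subjects)
    log: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "base_seed": config.base_seed,
        "n_subjects": len(subjects),
        "n_replicates": n_replicates,
        "chains": {},
        "failures": [],
        "degenerate_features": 0,
    }

    # --- baseline (unperturbed) features per subject/replicate -------------
    baseline_rows = []
    for subj in subjects:
        for r in range(n_replicates):
            row: dict = {"subject": subj.subject_id, "replicate": r}
            for s in proc.spacings:
                img, mask = interpolate_to_isotropic(
                    subj.images[r], subj.masks[r].as_fractional(), s, proc
                )
                vals, flags = _features_for_sample(img, mask, manifest, proc)
                row.update(vals)
                log["degenerate_features"] += len(flags)
            baseline_rows.append(row)
    baseline = pd.DataFrame(baseline_rows)

    # --- perturbation chains ------------------------------------------------
    sample_rows = []
    for label in config.chains:
        chain = PerturbationChain.from_label(label, config.chain_params.get(label))
        log["chains"][chain.label] = {"expansion": chain.size}
        for subj in subjects:
            for r in range(n_replicates):
                rep_seed = sample_seed(config.base_seed, f"{subj.subject_id}|rep{r}", ())
                noise_sd = (
                    estimate_noise_sd(subj.images[r])
                    if chain.spec("noise") is not None
                    else None
                )
                per_sample: dict[int, dict] = {}
                for s in proc.spacings:
                    try:
                        samples = expand_chain(
                            chain, subj.images[r], subj.masks[r], proc,
                            target_spacing=s, base_seed=rep_seed, noise_sd=noise_sd,
                        )
                    except RadperturbError as exc:
                        log["failures"].append(
                            f"{subj.subject_id}/rep{r}/{chain.label}@{s}mm: {exc}"
                        )
                        continue
                    for idx, smp in enumerate(samples):
                        row = per_sample.setdefault(
                            idx,
                            {
                                "subject": subj.subject_id,
                                "replicate": r,
                                "chain": chain.label,
                                "sample": idx,
                                "params": repr(smp.params),
                                "seed": smp.seed,
                            },
                        )
                        try:
                            vals, flags = _features_for_sample(smp.image, smp.mask, manifest, proc)
                            row.update(vals)
                            log["degenerate_features"] += len(flags)
                        except RadperturbError as exc:
                            log["failures"].append(
                                f"{subj.subject_id}/rep{r}/{chain.label}"
                                f"/sample{idx}@{s}mm: {exc}"
                            )
                sample_rows.extend(per_sample.values())
    features = pd.DataFrame(sample_rows)

    # --- ICC + classification ----------------------------------------------
    tr_table = None
    if n_replicates == 2:
        panels_tr = {}
        for fid in feature_cols:
            wide = baseline.pivot_table(
                index="subject", columns="replicate", values=fid, dropna=False
            ).dropna(axis=0, how="any")
            if wide.shape[0] >= 2 and wide.shape[1] == 2:
                panels_tr[fid] = wide.to_numpy()
        tr_table = _icc_table(
            [f for f in feature_cols if f in panels_tr], panels_tr,
            config.alpha, config.threshold,
        ).reindex(feature_cols)
        tr_table["label"] = tr_table["label"].fillna(INDETERMINATE)

    icc_tables: dict[str, pd.DataFrame] = {}
    comparisons: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for label in config.chains:
        label = label.upper()
        sub = features[features["chain"] == label]
        per_rep_panels: list[dict[str, np.ndarray]] = []
        for r in range(n_replicates):
            panels = {}
            rep_df = sub[sub["replicate"] == r]
            for fid in feature_cols:
                if fid not in rep_df.columns:
                    continue
                p = _panel(rep_df, fid)
                if p is not None:
                    panels[fid] = p
            per_rep_panels.append(panels)
        if n_replicates == 2:
            common = [
                f for f in feature_cols
                if f in per_rep_panels[0] and f in per_rep_panels[1]
            ]
            table = _icc_table(
                common, per_rep_panels[0], config.alpha, config.threshold,
                panels2=per_rep_panels[1],
            ).reindex(feature_cols)
        else:
            common = [f for f in feature_cols if f in per_rep_panels[0]]
            table = _icc_table(
                common, per_rep_panels[0], config.alpha, config.threshold
            ).reindex(feature_cols)
        table["label"] = table["label"].fillna(INDETERMINATE)
        icc_tables[label] = table

        counts = table["label"].value_counts()
        total = len(table)
        summary_rows.append(
            {
                "chain": label,
                "n_features": total,
                "robust": int(counts.get("robust", 0)),
                "non_robust": int(counts.get("non_robust", 0)),
                "indeterminate": int(counts.get("indeterminate", 0)),
                "fraction_robust": counts.get("robust", 0) / total,
                "fraction_non_robust": counts.get("non_robust", 0) / total,
                "fraction_indeterminate": counts.get("indeterminate", 0) / total,
            }
        )

        if tr_table is not None:
            comp_rows = []
            for fid in feature_cols:
                rec = compare_conditions(
                    tr_table.loc[fid, "label"], table.loc[fid, "label"], fid
                )
                comp_rows.append(
                    {
                        "feature": fid,
                        "test_retest": rec.test_retest,
                        "perturbation": rec.perturbation,
                        "category": rec.category,
                        "sub_state": rec.sub_state,
                    }
                )
            comparisons[label] = pd.DataFrame(comp_rows).set_index("feature")

    summary = pd.DataFrame(summary_rows)
    log["wall_time_s"] = round(time.time() - t0, 3)

    result = RunResult(features, baseline, icc_tables, summary, comparisons, log)
    if config.out_dir:
        _write_outputs(result, config, tr_table)
    return result


def _write_outputs(result: RunResult, config: RunConfig, tr_table) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.feature_table.to_csv(out / "features.csv", index=False)
    result.baseline_table.to_csv(out / "features_baseline.csv", index=False)
    for label, table in result.icc_tables.items():
        table.to_csv(out / f"icc_{label}.csv")
    if tr_table is not None:
        tr_table.to_csv(out / "icc_test_retest.csv")
    result.summary.to_csv(out / "summary.csv", index=False)
    for label, comp in result.comparisons.items():
        comp.to_csv(out / f"comparison_{label}.csv")
    with open(out / "run_log.json", "w") as fh:
        json.dump(result.log, fh, indent=2, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
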