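"""Study orchestration: simulate -> fit -> quantify -> compare.

Each stage runs standalone on an on-disk cohort directory (see the CLI), and
:func:`analyze_animal` provides the same fit + quantify chain in memory for
programmatic use.  Every run writes its resolved configuration beside the
outputs; all randomness derives from the single study seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import studyio
from .agreement import anova_bonferroni, bland_altman, group_summary, paired_t
from .asl import PerfusionInputs, compute_perfusion_map, perfusion_qc
from .containers import ASLConstants
from .phantom import (AcquisitionSettings, AnimalDataset, GroupSpec, default_groups,
                      generate_cohort)
from .regional import (ThresholdSettings, aar_from_t1, aar_from_t2, aar_is_from_asl,
                       assemble_metrics, delineate_lge, planimetry)
from .relaxometry import FitOptions, fit_t1_map, fit_t2_map

log = logging.getLogger(__name__)

#: modality -> (metric column, histology reference column) used in comparisons
MODALITY_PAIRS = {
    "LGE": ("lge_is_lv_pct", "hist_is_lv_pct"),
    "T2": ("t2_aar_lv_pct", "hist_aar_lv_pct"),
    "ASL_1SD": ("asl_1sd_aar_lv_pct", "hist_aar_lv_pct"),
    "ASL_2SD": ("asl_2sd_is_lv_pct", "hist_is_lv_pct"),
    "T1": ("t1_aar_lv_pct", "hist_aar_lv_pct"),
}


@dataclass
class StudyConfig:
    """Everything needed to reproduce a study run; YAML round-trippable."""

    groups: list = field(default_factory=default_groups)
    acquisition: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    constants: ASLConstants = field(default_factory=ASLConstants)
    fit: FitOptions = field(default_factory=FitOptions)
    thresholds: ThresholdSettings = field(default_factory=ThresholdSettings)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("t2_bounds_ms", "t1_star_bounds_s"):
            d["fit"][key] = list(d["fit"][key])
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown study-config key(s): {sorted(unknown)}")

        def build(klass, sub):
            if sub is None:
                return klass()
            names = {f.name for f in dataclasses.fields(klass)}
            bad = set(sub) - names
            if bad:
                raise ValueError(f"unknown key(s) for {klass.__name__}: {sorted(bad)}")
            return klass(**sub)

        groups = [build(GroupSpec, g) for g in d.get("groups", [])] or default_groups()
        fit_d = dict(d.get("fit") or {})
        for key in ("t2_bounds_ms", "t1_star_bounds_s"):
            if key in fit_d:
                fit_d[key] = tuple(fit_d[key])
        return cls(
            groups=groups,
            acquisition=build(AcquisitionSettings, d.get("acquisition")),
            constants=build(ASLConstants, d.get("constants")),
            fit=build(FitOptions, fit_d),
            thresholds=build(ThresholdSettings, d.get("thresholds")),
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        return cls.from_yaml(Path(path).read_text())


# ---------------------------------------------------------------------------
# in-memory analysis of one animal
# ---------------------------------------------------------------------------

def fit_animal(animal: AnimalDataset, fit: Optional[FitOptions] = None) -> dict:
    """Fit all parameter maps of one animal.

    Returns {"t2": ParameterMap, "t1_selective", "t1_global", "perfusion"}.
    The IR maps are fitted over myocardium plus blood pool (the blood ROI of
    the global map feeds the input function); perfusion combines the two
    scopes with the bpMBF formula.
    """
    fit = fit or FitOptions()
    myo7 = animal.labels_cmr.myocardium_mask
    t2_map = fit_t2_map(animal.t2_stack, myo7, fit)
    ir_mask = animal.labels_asl.myocardium_mask | animal.labels_asl.blood_mask
    t1_sel = fit_t1_map(animal.ir_selective, ir_mask, fit)
    t1_glob = fit_t1_map(animal.ir_global, ir_mask, fit)
    pmap = compute_perfusion_map(PerfusionInputs(
        t1_sel, t1_glob, animal.constants, blood_mask=animal.labels_asl.blood_mask))
    return {"t2": t2_map, "t1_selective": t1_sel, "t1_global": t1_glob, "perfusion": pmap}


def quantify_animal(animal: AnimalDataset, maps: dict,
                    thresholds: Optional[ThresholdSettings] = None) -> dict:
    """Regional metrics row (one animal, all modalities + ground truth)."""
    thresholds = thresholds or ThresholdSettings()
    myo7 = animal.labels_cmr.myocardium_mask
    myo6 = animal.labels_asl.myocardium_mask
    hist = planimetry(animal.histology)
    t2_res = aar_from_t2(maps["t2"], myo7, thresholds)
    lge_res = delineate_lge(animal.lge_stack, myo7, thresholds)
    asl_res = aar_is_from_asl(maps["perfusion"], myo6, thresholds)
    t1_res = aar_from_t1(maps["t1_global"], myo6, thresholds)
    qc = perfusion_qc(maps["perfusion"])
    row = {
        "animal_id": animal.animal_id,
        "group": animal.group,
        "hist_is_lv_pct": hist["is_lv_pct"],
        "hist_aar_lv_pct": hist["aar_lv_pct"],
        "hist_is_aar_pct": hist["is_aar_pct"],
        "lge_is_lv_pct": lge_res.area_fraction_pct,
        "t2_aar_lv_pct": t2_res.area_fraction_pct,
        "asl_1sd_aar_lv_pct": asl_res["aar"].area_fraction_pct,
        "asl_2sd_is_lv_pct": asl_res["is"].area_fraction_pct,
        "t1_aar_lv_pct": t1_res.area_fraction_pct,
        "t2_invalid_px": t2_res.n_invalid,
        "asl_invalid_px": asl_res["aar"].n_invalid,
        "asl_negative_px": qc.n_negative,
        "normal_t2_ms": t2_res.roi_stats.mean,
        "normal_perfusion": asl_res["aar"].roi_stats.mean,
        "normal_t1_s": t1_res.roi_stats.mean,
    }
    for k, v in animal.truth.items():
        row[f"true_{k}"] = v
    return row


def analyze_animal(animal: AnimalDataset, fit: Optional[FitOptions] = None,
                   thresholds: Optional[ThresholdSettings] = None) -> dict:
    """fit + quantify in one call; returns the metrics row."""
    return quantify_animal(animal, fit_animal(animal, fit), thresholds)


def analyze_cohort(animals: list, fit: Optional[FitOptions] = None,
                   thresholds: Optional[ThresholdSettings] = None) -> pd.DataFrame:
    return assemble_metrics([analyze_animal(a, fit, thresholds) for a in animals])


def run_study_in_memory(config: Optional[StudyConfig] = None) -> pd.DataFrame:
    """Simulate + analyze the whole configured study; returns the metrics table."""
    config = config or StudyConfig()
    animals = generate_cohort(config.groups, config.seed, config.acquisition,
                              config.constants)
    return analyze_cohort(animals, config.fit, config.thresholds)


# ---------------------------------------------------------------------------
# on-disk stages
# ---------------------------------------------------------------------------

def _write_config(config: StudyConfig, outdir: Path) -> None:
    text = config.to_yaml()
    (outdir / "study_config.yaml").write_text(text)


def simulate_study(config: StudyConfig, outdir) -> pd.DataFrame:
    """Write the simulated cohort (stacks, labels, truth) and its manifest."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {outdir}: {e}") from e
    _write_config(config, outdir)
    animals = generate_cohort(config.groups, config.seed, config.acquisition,
                              config.constants)
    rows = []
    for a in animals:
        adir = outdir / "animals" / a.animal_id
        adir.mkdir(parents=True, exist_ok=True)
        studyio.save_labels(adir / "labels_cmr.nii", a.labels_cmr)
        studyio.save_labels(adir / "labels_asl.nii", a.labels_asl)
        studyio.save_labels(adir / "histology.nii", a.histology)
        prov = {"config_sha256": studyio.config_hash(config.to_yaml()),
                "animal_seed": a.seed}
        studyio.save_stack(adir / "t2_series.nii", a.t2_stack, prov)
        studyio.save_stack(adir / "lge.nii", a.lge_stack, prov)
        studyio.save_stack(adir / "ir_selective.nii", a.ir_selective, prov)
        studyio.save_stack(adir / "ir_global.nii", a.ir_global, prov)
        studyio.write_json(adir / "truth.json",
                           {"group": a.group, "seed": a.seed, **a.truth})
        rows.append({"animal_id": a.animal_id, "group": a.group, "seed": a.seed,
                     **{f"true_{k}": v for k, v in a.truth.items()}})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    log.info("simulated %d animals into %s", len(rows), outdir)
    return manifest


def _load_animal(adir: Path) -> AnimalDataset:
    truth = studyio.read_json(adir / "truth.json")
    group = truth.pop("group")
    seed = truth.pop("seed")
    return AnimalDataset(
        animal_id=adir.name, group=group,
        labels_cmr=studyio.load_labels(adir / "labels_cmr.nii"),
        labels_asl=studyio.load_labels(adir / "labels_asl.nii"),
        histology=studyio.load_labels(adir / "histology.nii"),
        t2_stack=studyio.load_stack(adir / "t2_series.nii"),
        lge_stack=studyio.load_stack(adir / "lge.nii"),
        ir_selective=studyio.load_stack(adir / "ir_selective.nii"),
        ir_global=studyio.load_stack(adir / "ir_global.nii"),
        tissue_params=None, constants=ASLConstants(), truth=truth, seed=seed)


def fit_study(outdir, force: bool = False,
              config: Optional[StudyConfig] = None) -> None:
    """Fit T2/T1/perfusion maps for every simulated animal; skips complete ones."""
    outdir = Path(outdir)
    config = config or StudyConfig.from_file(outdir / "study_config.yaml")
    for adir in sorted((outdir / "animals").iterdir()):
        mdir = outdir / "maps" / adir.name
        done = mdir / "fit_log.json"
        if done.exists() and not force:
            log.info("maps for %s already complete, skipping (use force to refit)", adir.name)
            continue
        animal = _load_animal(adir)
        animal = dataclasses.replace(animal, constants=config.constants)
        maps = fit_animal(animal, config.fit)
        mdir.mkdir(parents=True, exist_ok=True)
        studyio.save_map(mdir / "t2_map.nii", maps["t2"])
        studyio.save_map(mdir / "t1_selective.nii", maps["t1_selective"])
        studyio.save_map(mdir / "t1_global.nii", maps["t1_global"])
        studyio.save_map(mdir / "perfusion.nii", maps["perfusion"])
        qc = perfusion_qc(maps["perfusion"])
        studyio.write_json(done, {
            "t2_invalid": int(maps["t2"].diagnostics.get("n_invalid", 0)),
            "t1_selective_invalid": int(maps["t1_selective"].diagnostics.get("n_invalid", 0)),
            "t1_global_invalid": int(maps["t1_global"].diagnostics.get("n_invalid", 0)),
            "perfusion_qc": qc.as_dict(),
        })
        log.info("fitted maps for %s", adir.name)


def quantify_study(outdir, config: Optional[StudyConfig] = None) -> pd.DataFrame:
    """Assemble the per-animal regional metrics table from fitted maps."""
    outdir = Path(outdir)
    config = config or StudyConfig.from_file(outdir / "study_config.yaml")
    rows = []
    for adir in sorted((outdir / "animals").iterdir()):
        animal = _load_animal(adir)
        animal = dataclasses.replace(animal, constants=config.constants)
        mdir = outdir / "maps" / adir.name
        maps = {"t2": studyio.load_map(mdir / "t2_map.nii"),
                "t1_selective": studyio.load_map(mdir / "t1_selective.nii"),
                "t1_global": studyio.load_map(mdir / "t1_global.nii"),
                "perfusion": studyio.load_map(mdir / "perfusion.nii")}
        rows.append(quantify_animal(animal, maps, config.thresholds))
    df = assemble_metrics(rows)
    df.to_csv(outdir / "metrics.csv", index=False)
    return df


def compare_study(outdir, metrics: Optional[pd.DataFrame] = None,
                  make_plots: bool = True) -> dict:
    """Per-group Bland-Altman + paired tests vs histology; across-group ANOVA."""
    outdir = Path(outdir)
    if metrics is None:
        metrics = pd.read_csv(outdir / "metrics.csv")
    cdir = outdir / "compare"
    cdir.mkdir(parents=True, exist_ok=True)
    agreement_rows = []
    for group, sub in metrics.groupby("group", sort=False):
        for modality, (mcol, rcol) in MODALITY_PAIRS.items():
            pairs = sub[[rcol, mcol]].dropna()
            if len(pairs) < 2:
                continue
            ref = pairs[rcol].to_numpy()
            met = pairs[mcol].to_numpy()
            ba = bland_altman(ref, met, "histology", modality)
            t = paired_t(ref, met)
            agreement_rows.append({
                "group": group, "modality": modality, "n": ba.n,
                "histology_mean": float(np.mean(ref)), "method_mean": float(np.mean(met)),
                "bias": ba.bias, "sd_diff": ba.sd_diff,
                "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                "paired_t": t.statistic, "paired_p": t.p,
            })
    agreement = pd.DataFrame(agreement_rows)
    agreement.to_csv(cdir / "agreement.csv", index=False)

    groups = [g.to_numpy(dtype=float)
              for _, g in metrics.groupby("group", sort=False)["hist_aar_lv_pct"]]
    labels = [str(g) for g, _ in metrics.groupby("group", sort=False)]
    anova_rows = []
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        for r in anova_bonferroni(groups, labels):
            anova_rows.append({"test": r.name, "groups": "|".join(r.groups or ()),
                               "statistic": r.statistic, "df": r.df, "p": r.p,
                               "p_adjusted": r.p_adjusted})
    pd.DataFrame(anova_rows).to_csv(cdir / "anova_hist_aar.csv", index=False)

    summary = group_summary(metrics, [m for m, _ in MODALITY_PAIRS.values()]
                            + ["hist_is_lv_pct", "hist_aar_lv_pct", "hist_is_aar_pct"])
    summary.to_csv(cdir / "group_summary.csv", index=False)

    if make_plots:
        from .plots import bland_altman_grid
        bland_altman_grid(metrics, MODALITY_PAIRS, cdir / "bland_altman.png")
    return {"agreement": agreement, "anova": pd.DataFrame(anova_rows), "summary": summary}


def run_study(config: StudyConfig, outdir, force: bool = False) -> dict:
    """simulate -> fit -> quantify -> compare, end to end."""
    simulate_study(config, outdir)
    fit_study(outdir, force=force, config=config)
    metrics = quantify_study(outdir, config=config)
    return compare_study(outdir, metrics)
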