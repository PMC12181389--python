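"""Six-configuration ablation harness with repeated k-fold cross-validation
and its statistical analysis (one-way ANOVA and Tukey HSD on per-replicate
test accuracy in percent).

Configurations (two factors: decision stack x input filter):

  #0  classical baseline (no QuantClass, no filter)
  #1  QuantClass + quanvolution 2x2
  #2  QuantClass + quanvolution 4x4
  #3  QuantClass only
  #4  no QuantClass + quanvolution 2x2 (classical network on filtered input)
  #5  no QuantClass + quanvolution 4x4

The "no QuantClass" factor switches the whole decision stack to the
classical baseline network; the filter factor switches what it sees.

Protocol: the test fold rotates through a stratified k-fold partition; each
fold re-partitions the remaining pool into train/validation (validation
about 10% of the full set); repeats re-seed the weight initialisation and
partitioning.  Every run trains for the fixed configured epoch count.  With
the default 10 folds x 10 repeats the six groups hold 100 replicates each,
so the ANOVA degrees of freedom are (5, 594).

Sums of squares, F, and the Tukey-Kramer statistics are computed here;
tail probabilities come from scipy's F and studentized-range
distributions.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import network
from .estimators import resize_images
from .quantvolution import QuantvolutionConfig, quantvolve_image
from .synthdata import LabeledDataset

__all__ = [
    "AblationSetting",
    "AblationConfig",
    "AnovaResult",
    "TukeyRow",
    "run_ablation",
    "summarize",
    "anova_oneway",
    "tukey_hsd",
    "pairwise_mean_differences",
    "report",
]


@dataclass(frozen=True)
class AblationSetting:
    config_id: int
    label: str
    quantclass: bool
    quantvolution: int | None  # None, 2 or 4


DEFAULT_SETTINGS = (
    AblationSetting(0, "no QuantClass + no filter", False, None),
    AblationSetting(1, "QuantClass + quanvolution 2x2", True, 2),
    AblationSetting(2, "QuantClass + quanvolution 4x4", True, 4),
    AblationSetting(3, "QuantClass only", True, None),
    AblationSetting(4, "no QuantClass + quanvolution 2x2", False, 2),
    AblationSetting(5, "no QuantClass + quanvolution 4x4", False, 4),
)


@dataclass
class AblationConfig:
    folds: int = 10
    repeats: int = 10
    epochs: int = 100
    batch_size: int = 32
    label_noise: float = 0.05
    resize: tuple[int, int] = (32, 215)
    head_mode: str = "functional"
    n_angles: int = 2
    base_seed: int = 0
    settings: tuple[AblationSetting, ...] = DEFAULT_SETTINGS

    def __post_init__(self) -> None:
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")
        if len(self.settings) != 6:
            raise ValueError("the ablation compares exactly 6 configurations")


def _features_for(setting: AblationSetting, images: np.ndarray,
                  cache: dict) -> np.ndarray:
    """Model-input stack for one configuration, cached across folds/repeats."""
    key = setting.quantvolution
    if key not in cache:
        if key is None:
            cache[key] = images[..., None]
        else:
            cfg = QuantvolutionConfig(k=key)
            cache[key] = np.stack([quantvolve_image(img, cfg) for img in images])
    return cache[key]


def run_ablation(dataset: LabeledDataset, cfg: AblationConfig) -> pd.DataFrame:
    """One row of replicate metrics per (configuration, fold, repeat)."""
    from sklearn.model_selection import StratifiedKFold, train_test_split

    x_all, y_all = dataset.arrays(None)
    n = len(y_all)
    if cfg.folds > np.bincount(y_all, minlength=4).min():
        raise ValueError("fold count exceeds the smallest per-class count")
    images = resize_images(x_all, cfg.resize)
    cache: dict = {}
    n_val = max(4, int(round(0.1 * n)))
    rows = []
    for setting in cfg.settings:
        feats = _features_for(setting, images, cache)
        for repeat in range(cfg.repeats):
            skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True,
                                  random_state=cfg.base_seed + repeat)
            for fold, (pool_idx, test_idx) in enumerate(skf.split(images, y_all)):
                seed = cfg.base_seed + 100_000 * setting.config_id + 100 * repeat + fold
                strat = y_all[pool_idx] if np.bincount(y_all[pool_idx], minlength=4).min() >= 2 else None
                tr_idx, va_idx = train_test_split(pool_idx, test_size=n_val,
                                                  random_state=seed, stratify=strat)
                spec = _model_spec(setting, feats.shape[1:], cfg)
                model = network.build_model(spec, seed=seed)
                tcfg = network.TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                                           label_noise=cfg.label_noise, seed=seed)
                ds = network.ArrayDataset(feats[tr_idx], y_all[tr_idx],
                                          feats[va_idx], y_all[va_idx],
                                          feats[test_idx], y_all[test_idx])
                res = network.train(model, ds, tcfg)
                rows.append({
                    "config": setting.config_id, "label": setting.label,
                    "fold": fold, "repeat": repeat,
                    "train_loss": res.train_loss, "train_accuracy": res.train_accuracy,
                    "val_loss": res.val_loss, "val_accuracy": res.val_accuracy,
                    "test_loss": res.test_loss, "test_accuracy": res.test_accuracy,
                    "seconds": res.seconds, "seed": seed,
                })
    return pd.DataFrame(rows)


def _model_spec(setting: AblationSetting, input_shape, cfg: AblationConfig) -> network.ModelSpec:
    # two-factor design: the "QuantClass" factor switches the whole decision
    # stack (hybrid conv/bn trunk + quantum head vs the classical baseline
    # network), the filter factor switches the input representation
    if not setting.quantclass:
        return network.ModelSpec(kind="classical", input_shape=tuple(input_shape))
    return network.ModelSpec(kind="hybrid", input_shape=tuple(input_shape),
                             head="quantclass", head_mode=cfg.head_mode,
                             n_angles=cfg.n_angles)


def summarize(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-configuration mean and sample std (n-1) of every metric."""
    metrics = ["train_loss", "train_accuracy", "val_loss", "val_accuracy",
               "test_loss", "test_accuracy", "seconds"]
    counts = rows.groupby("config").size()
    if (counts < 2).any():
        raise ValueError("need at least 2 replicates per configuration for a std")
    agg = rows.groupby("config")[metrics].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


@dataclass
class AnovaResult:
    ss_between: float
    df_between: int
    ss_within: float
    df_within: int
    f_stat: float
    p_value: float

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within


@dataclass
class TukeyRow:
    group1: int
    group2: int
    mean_diff: float  # mean(group2) - mean(group1)
    p_value: float
    ci_low: float
    ci_high: float
    significant: bool


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    return gs


def anova_oneway(groups) -> AnovaResult:
    """Standard one-way decomposition; F = MS_between / MS_within, upper-tail
    p from the F distribution."""
    gs = _check_groups(groups)
    all_values = np.concatenate(gs)
    grand = all_values.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_between = len(gs) - 1
    df_within = all_values.size - len(gs)
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        f_stat = 0.0 if ss_between == 0.0 else math.inf
    else:
        f_stat = (ss_between / df_between) / ms_within
    p = float(stats.f.sf(f_stat, df_between, df_within)) if math.isfinite(f_stat) else 0.0
    return AnovaResult(float(ss_between), df_between, float(ss_within), df_within,
                       float(f_stat), p)


def pairwise_mean_differences(means) -> dict[tuple[int, int], float]:
    """mean(group j) - mean(group i) for every unordered pair i < j, in the
    listed order (the sign convention of the Tukey table)."""
    means = list(means)
    return {(i, j): means[j] - means[i]
            for i, j in itertools.combinations(range(len(means)), 2)}


def tukey_hsd(groups, alpha: float = 0.05) -> list[TukeyRow]:
    """All-pairs Tukey HSD (Tukey-Kramer standard error for unequal n);
    p-values and critical values from the studentized range distribution
    with df = N - g."""
    gs = _check_groups(groups)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    anova = anova_oneway(gs)
    msw = anova.ms_within
    g = len(gs)
    df = anova.df_within
    means = [gr.mean() for gr in gs]
    diffs = pairwise_mean_differences(means)
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, g, df))
    out = []
    for (i, j), diff in diffs.items():
        se = math.sqrt(msw / 2.0 * (1.0 / gs[i].size + 1.0 / gs[j].size))
        if se == 0.0:
            p = 1.0 if diff == 0.0 else 0.0
            half = 0.0
        else:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, g, df))
            half = q_crit * se
        out.append(TukeyRow(group1=i, group2=j, mean_diff=float(diff), p_value=p,
                            ci_low=float(diff - half), ci_high=float(diff + half),
                            significant=bool(p < alpha)))
    return out


def report(summary: pd.DataFrame, anova: AnovaResult, tukey: list[TukeyRow],
           directory: str) -> dict[str, str]:
    """Write summary/ANOVA/Tukey CSV tables plus a JSON bundle with
    deterministic field ordering; returns the file paths."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "summary": os.path.join(directory, "summary.csv"),
        "anova": os.path.join(directory, "anova.csv"),
        "tukey": os.path.join(directory, "tukey.csv"),
        "json": os.path.join(directory, "report.json"),
    }
    summary.to_csv(paths["summary"], index=False)
    anova_df = pd.DataFrame([
        {"source": "between", "sum_sq": anova.ss_between, "df": anova.df_between,
         "F": anova.f_stat, "p_value": anova.p_value},
        {"source": "residual", "sum_sq": anova.ss_within, "df": anova.df_within,
         "F": float("nan"), "p_value": float("nan")},
    ])
    anova_df.to_csv(paths["anova"], index=False)
    tukey_df = pd.DataFrame([{
        "group1": r.group1, "group2": r.group2, "mean_diff": r.mean_diff,
        "p_value": r.p_value, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "significant": r.significant,
    } for r in tukey])
    tukey_df.to_csv(paths["tukey"], index=False)
    bundle = {
        "anova": {"ss_between": anova.ss_between, "df_between": anova.df_between,
                  "ss_within": anova.ss_within, "df_within": anova.df_within,
                  "F": anova.f_stat, "p_value": anova.p_value},
        "summary": json.loads(summary.to_json(orient="records")),
        "tukey": json.loads(tukey_df.to_json(orient="records")),
    }
    with open(paths["json"], "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    return paths
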