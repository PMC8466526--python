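"""Config-driven orchestration: synthesize or load spectra, preprocess,
run region PCA, amide-I deconvolution, per-cell band metrics and
two-group statistics, and write a reproducible report bundle.

A pipeline run is fully determined by its config and seed; rerunning
with the same pair produces byte-identical tables.  The manifest records
the config hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .amide import deconvolve_amide_i
from .chemometrics import run_pca
from .metrics import bh_index, peak_ratio, unsaturation_index
from .spectra import REGIONS, Region, SpectrumSet, load_spectra, save_spectra
from .synth import default_model, generate_population

__all__ = [
    "GroupComparison",
    "compare_groups_ttest",
    "significance_stars",
    "viability_percent",
    "PipelineConfig",
    "run_pipeline",
]


def significance_stars(p: float) -> str:
    """Stars at the 0.05 / 0.01 / 0.001 thresholds (strict inequalities:
    p exactly 0.05 is not significant)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    stars: str


def compare_groups_ttest(values_a, values_b, metric: str = "",
                         group_a: str = "A", group_b: str = "B",
                         equal_var: bool = False) -> GroupComparison:
    """Two-sided t-test between two samples (Welch by default).

    Two constant, equal samples give t = 0, p = 1 by convention rather
    than a 0/0 failure.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return GroupComparison(metric=metric, group_a=group_a, group_b=group_b,
                           mean_a=float(a.mean()), mean_b=float(b.mean()),
                           sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
                           n_a=int(a.size), n_b=int(b.size),
                           t_statistic=t, p_value=p, stars=significance_stars(p))


def viability_percent(a570_sample: float, a570_blank: float,
                      a570_control: float) -> float:
    """Cell viability (%) = (A570 sample - A570 blank)
    / (A570 control - A570 blank) x 100."""
    if a570_control == a570_blank:
        raise ValueError("control equals blank; viability undefined")
    return (a570_sample - a570_blank) / (a570_control - a570_blank) * 100.0


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """Declarative description of a full analysis run."""

    seed: int = 0
    out_dir: str = "results"
    input_path: str | None = None          # load spectra table if given,
    n_per_group: int = 50                  # else synthesize
    groups: list = field(default_factory=lambda: [
        ["GIC7", "control"], ["GIC7", "200uM"],
        ["PG88", "control"], ["PG88", "200uM"]])
    synth_overrides: dict = field(default_factory=dict)
    pca_regions: list = field(default_factory=lambda: [
        ["dna", "emsc_d2_uvn"], ["fingerprint", "emsc_snv"], ["lipids", "emsc_snv"]])
    pca_components: int = 3
    metrics: list = field(default_factory=lambda: [
        "bh_index", "unsaturation_index", "ch3_ch2_ratio"])
    comparisons: list = field(default_factory=lambda: [
        [["GIC7", "control"], ["GIC7", "200uM"]],
        [["PG88", "control"], ["PG88", "200uM"]]])

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_METRIC_FUNCS = {
    "bh_index": bh_index,
    "unsaturation_index": unsaturation_index,
    "ch3_ch2_ratio": peak_ratio,
}


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def _acquire(cfg: PipelineConfig) -> SpectrumSet:
    if cfg.input_path:
        return load_spectra(cfg.input_path)
    model = default_model(seed=cfg.seed, **cfg.synth_overrides)
    groups = [tuple(g) for g in cfg.groups]
    return generate_population(model, cfg.n_per_group, groups)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages and write the report bundle.

    Returns a manifest dict (also written as ``manifest.json``).  Any
    stage failure removes partial outputs and re-raises with the stage
    name.
    """
    out = Path(cfg.out_dir)
    if out.exists():
        shutil.rmtree(out)
    out.mkdir(parents=True)
    stage = "acquire"
    try:
        sset = _acquire(cfg)
        save_spectra(sset, out / "spectra.csv",
                     provenance=f"seed={cfg.seed} config={cfg.digest()}")
        artifacts = ["spectra.csv"]

        stage = "pca"
        for region_name, recipe in cfg.pca_regions:
            region = REGIONS[region_name] if isinstance(region_name, str) else Region(*region_name)
            res = run_pca(sset, region, recipe=recipe, k=cfg.pca_components)
            scores = pd.DataFrame(res.scores,
                                  columns=[f"PC{i+1}" for i in range(res.scores.shape[1])])
            scores = pd.concat([sset.labels, scores], axis=1)
            _fmt(scores, out / f"pca_{region.name}_scores.csv")
            loadings = pd.DataFrame(res.loadings.T, columns=[
                f"PC{i+1}" for i in range(res.loadings.shape[0])])
            loadings.insert(0, "wavenumber", res.wavenumbers)
            _fmt(loadings, out / f"pca_{region.name}_loadings.csv")
            expl = pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(res.explained))],
                                 "explained_fraction": res.explained})
            _fmt(expl, out / f"pca_{region.name}_explained.csv")
            artifacts += [f"pca_{region.name}_scores.csv",
                          f"pca_{region.name}_loadings.csv",
                          f"pca_{region.name}_explained.csv"]

        stage = "deconvolution"
        rows = []
        for cell_line, treatment in [tuple(g) for g in cfg.groups]:
            res = deconvolve_amide_i(sset, {"cell_line": cell_line,
                                            "treatment": treatment})
            row = {"cell_line": cell_line, "treatment": treatment}
            row.update(res.as_row())
            rows.append(row)
        _fmt(pd.DataFrame(rows), out / "amide_deconvolution.csv")
        artifacts.append("amide_deconvolution.csv")

        stage = "metrics"
        mrows = []
        for i in range(len(sset)):
            s = sset.spectrum(i)
            row = dict(sset.labels.iloc[i])
            for name in cfg.metrics:
                row[name] = _METRIC_FUNCS[name](s)
            mrows.append(row)
        metric_table = pd.DataFrame(mrows)
        _fmt(metric_table, out / "cell_metrics.csv")
        artifacts.append("cell_metrics.csv")

        stage = "statistics"
        crows = []
        for (line_a, treat_a), (line_b, treat_b) in [
                (tuple(a), tuple(b)) for a, b in cfg.comparisons]:
            sel_a = ((metric_table["cell_line"] == line_a)
                     & (metric_table["treatment"] == treat_a))
            sel_b = ((metric_table["cell_line"] == line_b)
                     & (metric_table["treatment"] == treat_b))
            for name in cfg.metrics:
                va = metric_table.loc[sel_a, name].dropna()
                vb = metric_table.loc[sel_b, name].dropna()
                cmp_res = compare_groups_ttest(
                    va, vb, metric=name,
                    group_a=f"{line_a}/{treat_a}", group_b=f"{line_b}/{treat_b}")
                crows.append(vars(cmp_res))
        _fmt(pd.DataFrame(crows), out / "group_comparisons.csv")
        artifacts.append("group_comparisons.csv")

        stage = "manifest"
        manifest = {"config": {k: v for k, v in cfg.__dict__.items()},
                    "config_digest": cfg.digest(), "seed": cfg.seed,
                    "version": __version__, "artifacts": artifacts}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8")
        return manifest
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
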