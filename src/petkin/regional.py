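"""Regional BPnd extraction, sex comparisons and VOI-level trait regressions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SubjectRecord, TCI_TRAITS, VoiAtlas
from .errors import ConfigurationError, ContractError
from .kinetics import ParametricImage

#: Thalamic subregion labels aggregated into the whole-thalamus row.
THALAMUS_SUBREGIONS = ("thalamus_AM", "thalamus_AL", "thalamus_CM",
                       "thalamus_CL", "thalamus_P")


def _split_side(region: str) -> tuple[str, str]:
    if region.endswith("_L"):
        return region[:-2], "L"
    if region.endswith("_R"):
        return region[:-2], "R"
    return region, ""


def extract_regional_bpnd(image: ParametricImage, atlas: VoiAtlas,
                          subject_id: str = "", statistic: str = "mean"
                          ) -> pd.DataFrame:
    """Per-region BPnd summary of a parametric image.

    Reports every atlas label, plus a pooled ``thalamus`` row over the five
    subregions. ``statistic`` is "mean" (standard VOI practice) or "median".
    """
    if image.bpnd_voxels.shape != atlas.labels.shape:
        raise ContractError("image and atlas grids differ")
    agg = np.mean if statistic == "mean" else np.median
    rows = []
    for lab, name in atlas.name_map.items():
        m = atlas.labels == lab
        if not m.any():
            warnings.warn(f"empty atlas label {name!r}; row omitted")
            continue
        base, side = _split_side(name)
        rows.append({"subject": subject_id, "region": name, "base_region": base,
                     "side": side, "bpnd": float(agg(image.bpnd_voxels[m]))})
    thal = np.zeros(atlas.labels.shape, dtype=bool)
    for sub in THALAMUS_SUBREGIONS:
        if sub in atlas.label_of:
            thal |= atlas.mask(sub)
    if thal.any():
        rows.append({"subject": subject_id, "region": "thalamus",
                     "base_region": "thalamus", "side": "",
                     "bpnd": float(agg(image.bpnd_voxels[thal]))})
    return pd.DataFrame(rows)


def build_regional_table(images: dict, atlas: VoiAtlas,
                         records: list[SubjectRecord]) -> pd.DataFrame:
    """Stack per-subject extractions and attach sex from the cohort records."""
    sex_of = {r.id: r.sex for r in records}
    parts = []
    for sid, img in images.items():
        if not isinstance(img, ParametricImage):
            img = ParametricImage(np.asarray(img), atlas.affine)
        t = extract_regional_bpnd(img, atlas, subject_id=sid)
        t["sex"] = sex_of.get(sid, "")
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


def sex_difference_tests(table: pd.DataFrame, equal_var: bool = False,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-region two-sample t-test (Welch by default), two-tailed."""
    out = []
    for region, grp in table.groupby("region"):
        f = grp.loc[grp["sex"] == "F", "bpnd"].to_numpy()
        m = grp.loc[grp["sex"] == "M", "bpnd"].to_numpy()
        if len(f) == 0 or len(m) == 0:
            raise ConfigurationError(f"region {region}: a sex group is absent")
        if np.ptp(np.concatenate([f, m])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(m, f, equal_var=equal_var)
        out.append({"region": region, "n_female": len(f), "n_male": len(m),
                    "mean_female": float(f.mean()), "mean_male": float(m.mean()),
                    "t": float(t), "p": float(p), "significant": bool(p < alpha)})
    return pd.DataFrame(out)


@dataclass
class RegressionResult:
    """Simple OLS of a trait score on regional BPnd."""

    trait: str
    region: str
    n: int
    slope: float
    intercept: float
    r2: float
    p: float                      # two-tailed

    @property
    def direction(self) -> str:
        return "positive" if self.slope >= 0 else "negative"


def _trait_value(rec: SubjectRecord, trait: str) -> float:
    if trait == "baq_total":
        return rec.baq_total
    if trait in TCI_TRAITS:
        return rec.tci[trait]
    raise ConfigurationError(f"unknown trait {trait!r}")


def voi_trait_regression(table: pd.DataFrame, records: list[SubjectRecord],
                         trait: str, region: str, sex_filter: str = "all"
                         ) -> RegressionResult:
    """OLS of the trait score on the region's BPnd mean across subjects."""
    sex_of = {r.id: r.sex for r in records}
    trait_of = {r.id: _trait_value(r, trait) for r in records}
    sub = table[table["region"] == region]
    if sex_filter in ("F", "M"):
        sub = sub[sub["subject"].map(sex_of) == sex_filter]
    if len(sub) < 3:
        raise ContractError("need at least 3 subjects for a regression")
    x = sub["bpnd"].to_numpy()
    y = sub["subject"].map(trait_of).to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ContractError("degenerate predictor: constant BPnd")
    res = stats.linregress(x, y)
    return RegressionResult(trait=trait, region=region, n=len(sub),
                            slope=float(res.slope), intercept=float(res.intercept),
                            r2=float(res.rvalue ** 2), p=float(res.pvalue))


def hormone_association_check(table: pd.DataFrame, records: list[SubjectRecord],
                              hormone: dict[str, float], sex_filter: str = "all",
                              alpha: float = 0.05, min_n: int = 3) -> dict:
    """Regress regional BPnd on a plasma hormone level, Bonferroni-corrected.

    ``hormone`` maps subject id to the measured level (NaN = unquantifiable).
    Regions with fewer than ``min_n`` quantifiable subjects are skipped with
    a warning, mirroring the small-n guard the assay limits force.
    """
    usable = {k: v for k, v in hormone.items() if np.isfinite(v)}
    if not usable:
        raise ConfigurationError("hormone column has no quantifiable values")
    sex_of = {r.id: r.sex for r in records}
    results, skipped = [], []
    regions = sorted(table["region"].unique())
    for region in regions:
        sub = table[table["region"] == region]
        if sex_filter in ("F", "M"):
            sub = sub[sub["subject"].map(sex_of) == sex_filter]
        sub = sub[sub["subject"].isin(usable)]
        if len(sub) < min_n:
            warnings.warn(f"region {region}: only {len(sub)} quantifiable "
                          "hormone values; skipped")
            skipped.append(region)
            continue
        x = np.array([usable[s] for s in sub["subject"]], dtype=float)
        y = sub["bpnd"].to_numpy()
        if np.ptp(x) == 0:
            skipped.append(region)
            continue
        res = stats.linregress(x, y)
        results.append({"region": region, "n": len(sub),
                        "slope": float(res.slope), "r2": float(res.rvalue ** 2),
                        "p": float(res.pvalue)})
    n_tests = max(len(results), 1)
    for r in results:
        r["p_bonferroni"] = min(r["p"] * n_tests, 1.0)
        r["significant"] = r["p_bonferroni"] < alpha
    return {"results": results, "skipped": skipped,
            "any_significant": any(r["significant"] for r in results)}
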