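"""File I/O, scenario configuration and the end-to-end pipeline.

Formats
-------
* NIfTI-1 4D diffusion volumes (X, Y, Z, B) with an FSL-style
  whitespace-separated b-value text file, and 3D ROI masks on the same
  voxel grid (nonzero = inside).
* CSV tables with unit-tagged headers: signal decays, per-ROI fits,
  long-format cohort tables and ROC result tables.  Readers validate the
  headers and refuse files with ambiguous units.
* JSON scenario files capturing a full synthetic study (groups, noise,
  thresholds, seed) so a simulation is reproducible from one file.

Masks and volumes are matched on the voxel grid only: a grid mismatch is
a hard error, never an implicit resample.  All floats are written with 17
significant digits so write/read round-trips are lossless and repeated
runs with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .model import THETA_DISPLAY_UNIT, DiffusionThresholds
from .fitting import SignalDecay, fit_adc_loglinear, per_bvalue_report
from .simulate import (
    DEFAULT_B_VALUES,
    GroupSpec,
    NoiseSpec,
    default_grading_groups,
    default_staging_groups,
    simulate_cohort,
)
from .stats import analyze_cohort

__all__ = [
    "FormatError",
    "read_bvals",
    "write_bvals",
    "read_dwi",
    "write_dwi",
    "reduce_roi",
    "DECAY_COLUMNS",
    "write_decays_csv",
    "read_decays_csv",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_results",
    "ScenarioConfig",
    "fit_decays",
    "fits_to_cohort",
    "run_pipeline",
]

FLOAT_FMT = "%.17g"

#: decay-table header; the b-value and signal columns carry unit tags
DECAY_COLUMNS = ("subject_id", "roi_id", "b_value_s_per_mm2", "mean_signal")
COHORT_COLUMNS = ("subject_id", "group", "b_value_s_per_mm2", "parameter", "value")


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


# ---------------------------------------------------------------- NIfTI


def read_bvals(path) -> list[float]:
    """Parse an FSL-style b-value file: whitespace-separated reals.

    Tolerates multiple spaces, tabs and Windows line endings; order is
    preserved.
    """
    text = Path(path).read_text()
    try:
        return [float(tok) for tok in text.split()]
    except ValueError as exc:
        raise FormatError(f"unparseable b-value file {path}: {exc}") from exc


def write_bvals(path, b_values) -> None:
    Path(path).write_text(" ".join(FLOAT_FMT % b for b in b_values) + "\n")


def read_dwi(nifti_path, bval_path):
    """Load a 4D DWI volume and its b-value schedule.

    Returns ``(volume, b_values)`` with the volume as a float array of
    shape (X, Y, Z, B).  The b-value count must equal the 4th dimension;
    a missing b = 0 entry triggers a warning because ADC and model
    fitting both need the unweighted reference.
    """
    img = nib.load(str(nifti_path))
    vol = np.asarray(img.get_fdata(), dtype=float)
    if vol.ndim != 4:
        raise FormatError(f"{nifti_path}: expected a 4D volume, got {vol.ndim}D")
    bvals = read_bvals(bval_path)
    if len(bvals) != vol.shape[3]:
        raise FormatError(
            f"b-value count mismatch: {len(bvals)} b-values vs "
            f"{vol.shape[3]} volumes"
        )
    if 0.0 not in bvals:
        warnings.warn(
            "b-value file contains no b=0 entry; ADC and model fitting "
            "require an unweighted reference",
            RuntimeWarning,
            stacklevel=2,
        )
    return vol, bvals


def write_dwi(nifti_path, volume, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(nifti_path))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    m = np.asarray(img.get_fdata())
    if m.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask, got {m.ndim}D")
    return m != 0


def reduce_roi(volume, mask, b_values, roi_id="roi", subject_id="subject") -> SignalDecay:
    """Mean ROI signal per b-value from a 4D volume and a 3D mask.

    Voxels where ``mask`` is nonzero are averaged at each b-value; the
    voxel count is recorded on the returned decay.  The mask must match
    the volume's spatial grid exactly (no resampling) and be nonempty.
    """
    vol = np.asarray(volume, dtype=float)
    m = np.asarray(mask) != 0
    if vol.ndim != 4:
        raise FormatError(f"expected 4D volume, got {vol.ndim}D")
    if m.shape != vol.shape[:3]:
        raise FormatError(
            f"mask grid {m.shape} does not match volume grid {vol.shape[:3]}"
        )
    n = int(m.sum())
    if n == 0:
        raise ValueError("mask selects no voxels")
    means = vol[m, :].mean(axis=0)
    return SignalDecay(
        b_values=tuple(float(b) for b in b_values),
        signals=tuple(means),
        roi_id=roi_id,
        subject_id=subject_id,
        n_voxels=n,
    )


# ------------------------------------------------------------------ CSV


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required columns {sorted(missing)}; "
            f"found {list(df.columns)} (unit-tagged headers are mandatory)"
        )


def write_decays_csv(path, decays: list[SignalDecay]) -> None:
    rows = [
        {
            "subject_id": d.subject_id,
            "roi_id": d.roi_id,
            "b_value_s_per_mm2": b,
            "mean_signal": s,
        }
        for d in decays
        for b, s in zip(d.b_values, d.signals)
    ]
    pd.DataFrame(rows, columns=list(DECAY_COLUMNS)).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_decays_csv(path) -> list[SignalDecay]:
    df = pd.read_csv(path)
    _require_columns(df, DECAY_COLUMNS, path)
    decays = []
    for (subj, roi), sub in df.groupby(["subject_id", "roi_id"], sort=True):
        sub = sub.sort_values("b_value_s_per_mm2")
        decays.append(
            SignalDecay(
                b_values=tuple(sub["b_value_s_per_mm2"]),
                signals=tuple(sub["mean_signal"]),
                roi_id=str(roi),
                subject_id=str(subj),
            )
        )
    return decays


def write_fits_csv(path, fits: pd.DataFrame, percent: bool = False) -> None:
    """Write a per-ROI fit table with unit-tagged headers.

    theta is converted to the 1e-4 mm^2/s display unit; fractions stay
    as [0, 1] proportions unless ``percent`` is set.
    """
    out = fits.copy()
    out["theta"] = out["theta"] / THETA_DISPLAY_UNIT
    frac_cols = ["f1", "f2", "f3", "f11", "f12", "f13"]
    suffix = "_pct" if percent else ""
    if percent:
        out[frac_cols] = out[frac_cols] * 100.0
    out = out.rename(
        columns={
            "b_value": "b_value_s_per_mm2",
            "adc": "adc_mm2_per_s",
            "theta": "theta_1e-4_mm2_per_s",
            **{c: c + suffix for c in frac_cols},
        }
    )
    out.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_cohort_csv(path, cohort: pd.DataFrame) -> None:
    out = cohort.rename(columns={"b_value": "b_value_s_per_mm2"})
    out[list(COHORT_COLUMNS)].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COHORT_COLUMNS, path)
    return df.rename(columns={"b_value_s_per_mm2": "b_value"})


def write_results(path_csv, results: pd.DataFrame, path_json=None) -> None:
    results.to_csv(path_csv, index=False, float_format=FLOAT_FMT)
    if path_json is not None:
        Path(path_json).write_text(
            json.dumps(results.to_dict(orient="records"), indent=2, default=float)
            + "\n"
        )


# ------------------------------------------------------------- scenario


@dataclass(frozen=True)
class ScenarioConfig:
    """A complete, JSON-serialisable synthetic-study description."""

    groups: tuple[GroupSpec, ...]
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    thresholds: DiffusionThresholds = field(default_factory=DiffusionThresholds)
    protocol: str = "fixed-theta"
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    percent: bool = False
    name: str = "scenario"

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "seed": self.seed,
            "protocol": self.protocol,
            "percent": self.percent,
            "b_values_s_per_mm2": list(self.b_values),
            "noise": dataclasses.asdict(self.noise),
            "thresholds_mm2_per_s": {
                "staging_low": self.thresholds.staging_low,
                "staging_high": self.thresholds.staging_high,
                "grading": list(self.thresholds.grading),
            },
            "groups": [dataclasses.asdict(g) for g in self.groups],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        try:
            payload = json.loads(text)
            thr = payload["thresholds_mm2_per_s"]
            return cls(
                groups=tuple(GroupSpec(**g) for g in payload["groups"]),
                b_values=tuple(float(b) for b in payload["b_values_s_per_mm2"]),
                thresholds=DiffusionThresholds(
                    staging_low=thr["staging_low"],
                    staging_high=thr["staging_high"],
                    grading=tuple(thr["grading"]),
                ),
                protocol=payload["protocol"],
                noise=NoiseSpec(**payload["noise"]),
                seed=int(payload["seed"]),
                percent=bool(payload.get("percent", False)),
                name=payload.get("name", "scenario"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"invalid scenario JSON: {exc}") from exc

    @classmethod
    def load(cls, path) -> "ScenarioConfig":
        return cls.from_json(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def default_staging_scenario(seed: int = 0) -> ScenarioConfig:
    """The bundled 24-vs-42-subject benign/malignant scenario."""
    return ScenarioConfig(groups=default_staging_groups(), seed=seed, name="default_staging")


def default_grading_scenario(seed: int = 0) -> ScenarioConfig:
    """The bundled 18-vs-24-subject low/high-grade scenario."""
    return ScenarioConfig(groups=default_grading_groups(), seed=seed, name="default_grading")


# ------------------------------------------------------------- pipeline


def fit_decays(
    decays: list[SignalDecay],
    protocol: str = "fixed-theta",
    thresholds: DiffusionThresholds | None = None,
) -> pd.DataFrame:
    """Per-b-value fit table for a list of decays (stacked rows)."""
    frames = [per_bvalue_report(d, protocol=protocol, thresholds=thresholds) for d in decays]
    return pd.concat(frames, ignore_index=True)


def fits_to_cohort(fits: pd.DataFrame, group_of: dict[str, str]) -> pd.DataFrame:
    """Reshape a fit table into the long cohort format for analysis.

    ``group_of`` maps subject_id to its group label.  Parameters carried
    into the cohort: adc, kappa and the six fractions (theta is omitted
    by default because it is shared across b-values under the default
    protocol and near-identical between groups).
    """
    params = ["adc", "kappa", "f1", "f2", "f3", "f11", "f12", "f13"]
    long = fits.melt(
        id_vars=["subject_id", "b_value"],
        value_vars=params,
        var_name="parameter",
        value_name="value",
    )
    long["group"] = long["subject_id"].map(group_of)
    if long["group"].isna().any():
        missing = sorted(long.loc[long["group"].isna(), "subject_id"].unique())
        raise ValueError(f"no group label for subjects: {missing}")
    return long[["subject_id", "group", "b_value", "parameter", "value"]]


def run_pipeline(config: ScenarioConfig, outdir) -> dict[str, Path]:
    """Simulate -> fit -> fractions -> analyze, writing every artifact.

    Writes decays.csv, truth.csv, fits.csv, cohort.csv, results.csv,
    results.json and a run_record.json capturing the resolved
    configuration; returns the paths keyed by artifact name.  Outputs
    are byte-identical across repeated runs with the same scenario.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    decays, truth = simulate_cohort(
        groups=config.groups, b_values=config.b_values, noise=config.noise,
        seed=config.seed,
    )
    paths = {
        "scenario": outdir / "scenario.json",
        "decays": outdir / "decays.csv",
        "truth": outdir / "truth.csv",
        "fits": outdir / "fits.csv",
        "cohort": outdir / "cohort.csv",
        "results_csv": outdir / "results.csv",
        "results_json": outdir / "results.json",
        "run_record": outdir / "run_record.json",
    }
    config.save(paths["scenario"])
    write_decays_csv(paths["decays"], decays)
    truth.to_csv(paths["truth"], index=False, float_format=FLOAT_FMT)

    fits = fit_decays(decays, protocol=config.protocol, thresholds=config.thresholds)
    write_fits_csv(paths["fits"], fits, percent=config.percent)

    group_of = dict(zip(truth["subject_id"], truth["group"]))
    cohort = fits_to_cohort(fits, group_of)
    write_cohort_csv(paths["cohort"], cohort)

    results = analyze_cohort(cohort)
    if config.percent:
        results = results.copy()
        results["sensitivity"] = results["sensitivity"] * 100.0
        results["specificity"] = results["specificity"] * 100.0
    write_results(paths["results_csv"], results, paths["results_json"])

    import gammadwi

    record = {
        "scenario": config.name,
        "seed": config.seed,
        "n_subjects": int(truth.shape[0]),
        "versions": {
            "gammadwi": gammadwi.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    paths["run_record"].write_text(json.dumps(record, indent=2) + "\n")
    return paths
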