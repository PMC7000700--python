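"""Primary-screen analysis for the 1536-well FLT-FRET assay.

Each screen run consists of three physically distinct 1536-well plates
sharing one layout: an unlabeled membrane plate (spectral-intensity
control), a donor-only plate (donor lifetime control) and the
donor-acceptor plate that carries the FRET readout.  Compounds occupy
columns 3-22 and 27-46 (1280 wells); DMSO controls occupy columns 1-2,
23-26 and 47-48 (256 wells).

The analysis chain is: per-plate FRET efficiency E = 1 - tau_DA/tau_D
(tau_D = donor-only DMSO mean), normalization E/E0 against the plate's
DMSO control mean E0, a 4-SD hit rule on E/E0 in control-SD units,
3-SD false-hit filters on the two companion plates, reproducibility
aggregation across runs, and quality control (Z' factor, Gaussian fit of
the null E/E0 distribution, hit rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .waveform import fret_efficiency

__all__ = [
    "PlateLayout",
    "PlateRun",
    "ScreenResult",
    "GaussianFit",
    "DEFAULT_LAYOUT",
    "normalize_plate",
    "filter_false_hits",
    "call_hits",
    "aggregate_reproducibility",
    "z_prime",
    "fit_control_gaussian",
    "hit_rate",
    "analyze_screen",
]

SAMPLE_TYPES = ("donor_acceptor", "donor_only", "unlabeled")


def _row_labels(n_rows: int) -> list[str]:
    """A..Z, AA, AB, ... (32 rows end at AF)."""
    labels = []
    for i in range(n_rows):
        if i < 26:
            labels.append(chr(ord("A") + i))
        else:
            labels.append("A" + chr(ord("A") + i - 26))
    return labels


@dataclass(frozen=True)
class PlateLayout:
    """Column-based plate layout with disjoint compound and control columns."""

    n_rows: int = 32
    n_cols: int = 48
    compound_cols: tuple = tuple(range(3, 23)) + tuple(range(27, 47))
    control_cols: tuple = (1, 2, 23, 24, 25, 26, 47, 48)

    def __post_init__(self) -> None:
        if set(self.compound_cols) & set(self.control_cols):
            raise ValueError("compound and control columns must be disjoint")
        all_cols = set(self.compound_cols) | set(self.control_cols)
        if not all_cols <= set(range(1, self.n_cols + 1)):
            raise ValueError("column indices out of range")

    @property
    def n_compound_wells(self) -> int:
        return self.n_rows * len(self.compound_cols)

    @property
    def n_control_wells(self) -> int:
        return self.n_rows * len(self.control_cols)

    def well_name(self, row: int, col: int) -> str:
        return f"{_row_labels(self.n_rows)[row]}{col:02d}"

    def well_table(self) -> pd.DataFrame:
        """One row per well: well, row, col, role, compound_id.

        Compound identifiers are assigned column-major (down each compound
        column in order), C0001..C1280 for the default layout.
        """
        rows = []
        labels = _row_labels(self.n_rows)
        counter = 0
        role_by_col = {c: "compound" for c in self.compound_cols}
        role_by_col.update({c: "control" for c in self.control_cols})
        compound_ids = {}
        for col in sorted(self.compound_cols):
            for r in range(self.n_rows):
                counter += 1
                compound_ids[(r, col)] = f"C{counter:04d}"
        for col in range(1, self.n_cols + 1):
            role = role_by_col.get(col)
            if role is None:
                continue
            for r in range(self.n_rows):
                rows.append(
                    {
                        "well": f"{labels[r]}{col:02d}",
                        "row": r,
                        "col": col,
                        "role": role,
                        "compound_id": compound_ids.get((r, col), "DMSO"),
                    }
                )
        return pd.DataFrame(rows)


DEFAULT_LAYOUT = PlateLayout()


@dataclass
class PlateRun:
    """One screen run: well records for the three sample-type plates.

    ``wells`` is a long-format table with columns
    read_time_min, sample_type, well, row, col, role, compound_id,
    tau_ns, intensity.
    """

    run_id: str
    wells: pd.DataFrame
    layout: PlateLayout = field(default_factory=PlateLayout)

    REQUIRED_COLUMNS = (
        "read_time_min",
        "sample_type",
        "well",
        "role",
        "compound_id",
        "tau_ns",
        "intensity",
    )

    def validate(self) -> None:
        missing = set(self.REQUIRED_COLUMNS) - set(self.wells.columns)
        if missing:
            raise ValueError(f"run {self.run_id}: missing columns {sorted(missing)}")
        bad = set(self.wells["sample_type"]) - set(SAMPLE_TYPES)
        if bad:
            raise ValueError(f"run {self.run_id}: unknown sample types {sorted(bad)}")
        dup = self.wells.duplicated(subset=["read_time_min", "sample_type", "well"])
        if dup.any():
            raise ValueError(f"run {self.run_id}: duplicate wells in plate table")
        cmpd = self.wells[self.wells["role"] == "compound"]
        if (cmpd["compound_id"] == "DMSO").any() or cmpd["compound_id"].isna().any():
            raise ValueError(f"run {self.run_id}: compound wells must carry a compound_id")

    @property
    def read_times(self) -> list[float]:
        return sorted(self.wells["read_time_min"].unique())

    def plate(self, sample_type: str, read_time: float | None = None) -> pd.DataFrame:
        if read_time is None:
            read_time = max(self.read_times)
        sub = self.wells[
            (self.wells["sample_type"] == sample_type)
            & (self.wells["read_time_min"] == read_time)
        ]
        if sub.empty:
            raise ValueError(
                f"run {self.run_id}: no {sample_type} plate at read time {read_time} min"
            )
        return sub


@dataclass
class GaussianFit:
    mu: float
    sigma: float
    n_used: int
    se_mu: float
    se_sigma: float


@dataclass
class ScreenResult:
    """Assembled screen output: per-compound-per-run table, reproducible
    hit list, and QC metrics."""

    per_compound: pd.DataFrame
    reproducible: pd.DataFrame
    qc: dict


def normalize_plate(run: PlateRun, read_time: float | None = None) -> pd.DataFrame:
    """Per-well FRET efficiency E and normalized E/E0 for one run.

    tau_D is the mean donor-only lifetime over that plate's DMSO wells
    (the donor-only and donor-acceptor plates are physically distinct, so
    no well-to-well pairing is attempted).  E0 is the mean E of the
    donor-acceptor plate's DMSO wells.
    """
    run.validate()
    donor = run.plate("donor_only", read_time)
    da = run.plate("donor_acceptor", read_time)

    donor_ctrl = donor.loc[donor["role"] == "control", "tau_ns"]
    if donor_ctrl.size < 8:
        raise ValueError(f"run {run.run_id}: fewer than 8 usable donor-only control wells")
    tau_d = float(donor_ctrl.mean())

    out = da.copy()
    out["E"] = fret_efficiency(out["tau_ns"].to_numpy(), tau_d)

    ctrl_e = out.loc[out["role"] == "control", "E"]
    if ctrl_e.size < 8:
        raise ValueError(f"run {run.run_id}: fewer than 8 usable DMSO control wells")
    e0 = float(ctrl_e.mean())
    if e0 <= 0:
        raise ValueError(f"run {run.run_id}: non-positive control FRET (E0={e0:.4g})")
    out["e_ratio"] = out["E"] / e0
    out.attrs["tau_d"] = tau_d
    out.attrs["e0"] = e0
    return out.reset_index(drop=True)


def _plate_flags(plate: pd.DataFrame, value_col: str, k_sd: float) -> pd.Series:
    ctrl = plate.loc[plate["role"] == "control", value_col]
    if ctrl.size < 8:
        raise ValueError("fewer than 8 control wells for artifact filtering")
    mu = float(ctrl.mean())
    sd = float(ctrl.std(ddof=1))
    cmpd = plate[plate["role"] == "compound"]
    dev = (cmpd[value_col] - mu).abs()
    flags = dev > k_sd * sd
    flags.index = cmpd["compound_id"].to_numpy()
    return flags


def filter_false_hits(
    run: PlateRun, k_sd: float = 3.0, read_time: float | None = None
) -> pd.DataFrame:
    """False-hit artifact flags from the two companion plates.

    A compound is flagged ``donor_only_artifact`` when its donor-only
    lifetime deviates from the donor-only DMSO mean by more than ``k_sd``
    control SDs (the compound perturbs the donor itself, not FRET), and
    ``intensity_artifact`` analogously on the unlabeled plate's
    integrated spectral intensity (the compound is fluorescent or
    scatters).  Flagged compounds are excluded from hit lists.
    """
    run.validate()
    donor = run.plate("donor_only", read_time)
    unlabeled = run.plate("unlabeled", read_time)
    d_flags = _plate_flags(donor, "tau_ns", k_sd)
    i_flags = _plate_flags(unlabeled, "intensity", k_sd)
    flags = pd.DataFrame({"donor_only_artifact": d_flags, "intensity_artifact": i_flags})
    flags["artifact"] = flags["donor_only_artifact"] | flags["intensity_artifact"]
    flags.index.name = "compound_id"
    return flags


def call_hits(
    normalized: pd.DataFrame,
    artifact_flags: pd.DataFrame | None = None,
    k_sd: float = 4.0,
) -> pd.DataFrame:
    """Per-compound hit calls on one normalized plate.

    A compound is a hit iff |E/E0 - mean_ctrl(E/E0)| strictly exceeds
    ``k_sd`` times the SD of the plate's DMSO-control E/E0 and the
    compound is not artifact-flagged.  The signed deviation in control-SD
    units (``delta_sd``) and direction are retained.
    """
    ctrl = normalized.loc[normalized["role"] == "control", "e_ratio"]
    mu_c = float(ctrl.mean())
    sd_c = float(ctrl.std(ddof=1))
    if sd_c == 0:
        raise ValueError("control SD of E/E0 is zero; hit threshold undefined")

    cmpd = normalized[normalized["role"] == "compound"].copy()
    cmpd["delta_sd"] = (cmpd["e_ratio"] - mu_c) / sd_c
    cmpd["sign"] = np.sign(cmpd["delta_sd"]).astype(int)
    cmpd["hit"] = cmpd["delta_sd"].abs() > k_sd

    if artifact_flags is not None:
        flagged = artifact_flags.reindex(cmpd["compound_id"])["artifact"].fillna(False)
        cmpd["donor_only_artifact"] = (
            artifact_flags.reindex(cmpd["compound_id"])["donor_only_artifact"]
            .fillna(False)
            .to_numpy()
        )
        cmpd["intensity_artifact"] = (
            artifact_flags.reindex(cmpd["compound_id"])["intensity_artifact"]
            .fillna(False)
            .to_numpy()
        )
        cmpd["hit"] = cmpd["hit"] & ~flagged.to_numpy()
    else:
        cmpd["donor_only_artifact"] = False
        cmpd["intensity_artifact"] = False

    keep = [
        "well",
        "compound_id",
        "E",
        "e_ratio",
        "delta_sd",
        "sign",
        "hit",
        "donor_only_artifact",
        "intensity_artifact",
    ]
    return cmpd[keep].reset_index(drop=True)


def aggregate_reproducibility(
    hits_by_run: Mapping[str, pd.DataFrame], min_runs: int = 2
) -> pd.DataFrame:
    """Cross-run reproducible hit list.

    A compound is reproducible iff it is a hit *with the same sign* in at
    least ``min_runs`` runs (opposite-direction flags are treated as
    artifacts, not reproduced biology).  The report carries the per-run
    E/E0 values, their mean and SE.
    """
    if len(hits_by_run) < 2:
        raise ValueError("need at least two runs to aggregate reproducibility")
    run_ids = list(hits_by_run)
    ref = set(hits_by_run[run_ids[0]]["compound_id"])
    for rid in run_ids[1:]:
        if set(hits_by_run[rid]["compound_id"]) != ref:
            raise ValueError(f"run {rid} has a mismatched compound library")

    long = pd.concat(
        [df.assign(run_id=rid) for rid, df in hits_by_run.items()], ignore_index=True
    )
    rows = []
    for cid, grp in long.groupby("compound_id", sort=True):
        pos = int(((grp["hit"]) & (grp["sign"] > 0)).sum())
        neg = int(((grp["hit"]) & (grp["sign"] < 0)).sum())
        n_hit = max(pos, neg)
        direction = 0
        if n_hit >= min_runs:
            direction = 1 if pos >= neg else -1
        ratios = grp["e_ratio"].to_numpy()
        rows.append(
            {
                "compound_id": cid,
                "n_runs_hit": n_hit,
                "n_runs_hit_any_sign": pos + neg,
                "direction": direction,
                "reproducible": n_hit >= min_runs,
                "mean_e_ratio": float(np.mean(ratios)),
                "se_e_ratio": float(np.std(ratios, ddof=1) / np.sqrt(len(ratios)))
                if len(ratios) > 1
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def z_prime(control_taus: Sequence[float], reference_taus: Sequence[float]) -> float:
    """Screening-window quality statistic Z'.

    Z' = 1 - 3*(sd_control + sd_reference)/|mean_reference - mean_control|,
    computed on the donor-acceptor lifetimes of DMSO-control wells versus
    reference wells (20 uM suramin, which abolishes FRET).  Z' >= 0.5
    indicates an HTS-ready assay.
    """
    c = np.asarray(control_taus, dtype=float)
    r = np.asarray(reference_taus, dtype=float)
    if c.size < 2 or r.size < 2:
        raise ValueError("need at least two wells per group")
    dmu = abs(float(r.mean()) - float(c.mean()))
    if dmu == 0:
        raise ValueError("group means are equal; Z' undefined")
    return 1.0 - 3.0 * (float(c.std(ddof=1)) + float(r.std(ddof=1))) / dmu


def fit_control_gaussian(
    values: Sequence[float],
    robust: bool = False,
    trim_z: float = 4.0,
    min_n: int = 50,
) -> GaussianFit:
    """Maximum-likelihood Gaussian fit of the central E/E0 distribution.

    With ``robust=True`` points beyond ``trim_z`` robust SDs
    (median/MAD-based) are trimmed before the ML fit, so a few large-
    effect hits do not inflate sigma.  Standard errors are the usual
    sigma/sqrt(n) and sigma/sqrt(2n).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} values, got {x.size}")
    if robust:
        med = float(np.median(x))
        mad_sigma = 1.4826 * float(np.median(np.abs(x - med)))
        if mad_sigma == 0:
            mad_sigma = float(np.std(x)) or 1.0
        x = x[np.abs(x - med) <= trim_z * mad_sigma]
    mu, sigma = stats.norm.fit(x)
    if sigma == 0:
        warnings.warn("degenerate Gaussian fit: sigma = 0", RuntimeWarning, stacklevel=2)
    n = x.size
    return GaussianFit(
        mu=float(mu),
        sigma=float(sigma),
        n_used=int(n),
        se_mu=float(sigma / np.sqrt(n)),
        se_sigma=float(sigma / np.sqrt(2 * n)),
    )


def hit_rate(n_hits: int, library_size: int) -> float:
    """Fraction of the library called as hits in one run."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return n_hits / library_size


def analyze_screen(
    runs: Sequence[PlateRun],
    k_sd_hit: float = 4.0,
    k_sd_filter: float = 3.0,
    min_runs: int = 2,
    read_time: float | None = None,
    robust_gaussian: bool = True,
) -> ScreenResult:
    """Full primary-screen analysis across runs.

    Composes normalization, artifact filtering, hit calling,
    reproducibility aggregation and QC (per-run hit rates plus a Gaussian
    fit of the pooled compound-well E/E0 distribution; robust trimming is
    on by default so genuine hits do not inflate the width estimate).
    """
    per_run = {}
    rates = {}
    pooled = []
    for run in runs:
        norm = normalize_plate(run, read_time)
        flags = filter_false_hits(run, k_sd=k_sd_filter, read_time=read_time)
        hits = call_hits(norm, flags, k_sd=k_sd_hit)
        per_run[run.run_id] = hits
        rates[run.run_id] = hit_rate(int(hits["hit"].sum()), len(hits))
        pooled.append(hits["e_ratio"].to_numpy())

    reproducible = aggregate_reproducibility(per_run, min_runs=min_runs)
    gauss = fit_control_gaussian(np.concatenate(pooled), robust=robust_gaussian)

    per_compound = pd.concat(
        [df.assign(run_id=rid) for rid, df in per_run.items()], ignore_index=True
    )
    qc = {
        "hit_rate": rates,
        "gaussian_mu": gauss.mu,
        "gaussian_sigma": gauss.sigma,
        "gaussian_n": gauss.n_used,
        "gaussian_se_mu": gauss.se_mu,
        "gaussian_se_sigma": gauss.se_sigma,
        "k_sd_hit": k_sd_hit,
        "k_sd_filter": k_sd_filter,
        "min_runs": min_runs,
    }
    return ScreenResult(per_compound=per_compound, reproducible=reproducible, qc=qc)
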