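"""End-to-end study orchestration.

Calibrate the two predictive equations on an extant specimen table,
quantify accuracy/precision with percent prediction error (PPE), estimate
fossil body masses with both methods and compare them, and run the
centre-of-mass (CoM) proportion study across model variants (bare hulls,
MEF/SEF-expanded, trunk-deflated).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .allometry import (
    PPEReport,
    ScalingFit,
    fit_loglog,
    mean_ppe_ci,
    ppe,
    predict_mass_mch,
    predict_mass_ss,
    subsample_mean_ppe,
)
from .body_model import (
    BodyModel,
    ExpansionFactorTable,
    apply_expansion,
    com_metrics,
    deflate_trunk,
)
from .published import DEFAULT_DENSITY, FOSSIL_MASS_TABLE

logger = logging.getLogger("hullmass")

__all__ = [
    "SpecimenRecord",
    "FossilEstimateRow",
    "StudyConfig",
    "SpecimenTableError",
    "load_specimen_table",
    "records_to_frame",
    "calibrate",
    "estimate_fossils",
    "accuracy_report",
    "method_discrepancy_fit",
    "com_study",
    "published_fossil_rows",
    "write_fossil_table",
]

_CLADES = {"mammal", "crocodylian", "other_reptile", "fossil"}
_REQUIRED_COLUMNS = {"species", "clade"}
_NUMERIC_COLUMNS = (
    "known_mass_kg",
    "mch_volume_m3",
    "humerus_circ_mm",
    "femur_circ_mm",
    "humerus_len_mm",
    "femur_len_mm",
)


class SpecimenTableError(ValueError):
    """A specimen CSV violates the schema or row invariants."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One individual: identity, mass, hull volume and limb-bone dimensions.

    Any numeric field may be absent (None) except that a record must carry
    either a hull volume or a circumference pair to be usable;
    ``mass_provenance`` distinguishes directly measured masses from masses
    approximated by species-specific literature scaling.
    """

    species: str
    clade: str
    known_mass_kg: float | None = None
    mch_volume_m3: float | None = None
    humerus_circ_mm: float | None = None
    femur_circ_mm: float | None = None
    humerus_len_mm: float | None = None
    femur_len_mm: float | None = None
    mass_provenance: str = "measured"

    def __post_init__(self) -> None:
        if self.clade not in _CLADES:
            raise SpecimenTableError(
                f"{self.species}: unknown clade {self.clade!r}; expected one of {sorted(_CLADES)}"
            )
        for name in _NUMERIC_COLUMNS:
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise SpecimenTableError(f"{self.species}: {name} must be > 0, got {value}")
        has_circ_pair = self.humerus_circ_mm is not None and self.femur_circ_mm is not None
        if self.mch_volume_m3 is None and not has_circ_pair:
            raise SpecimenTableError(
                f"{self.species}: needs a hull volume or a humerus+femur circumference pair"
            )
        if self.mass_provenance not in {"measured", "literature_scaling"}:
            raise SpecimenTableError(
                f"{self.species}: mass_provenance must be 'measured' or 'literature_scaling'"
            )

    @property
    def combined_circ_mm(self) -> float | None:
        if self.humerus_circ_mm is None or self.femur_circ_mm is None:
            return None
        return self.humerus_circ_mm + self.femur_circ_mm

    @property
    def combined_len_mm(self) -> float | None:
        if self.humerus_len_mm is None or self.femur_len_mm is None:
            return None
        return self.humerus_len_mm + self.femur_len_mm


@dataclass(frozen=True)
class FossilEstimateRow:
    """Both mass estimates for one fossil taxon plus their ratio."""

    species: str
    log10_mch: float | None
    mch_kg: float | None
    log10_ss: float | None
    ss_kg: float | None
    ratio_ss_mch: float | None

    def rounded_ratio(self, ndigits: int = 1) -> float | None:
        """Ratio at reporting precision (full precision kept internally)."""
        return None if self.ratio_ss_mch is None else round(self.ratio_ss_mch, ndigits)


@dataclass(frozen=True)
class StudyConfig:
    """Run-wide configuration: physical constants, sampling, variants."""

    density: float = DEFAULT_DENSITY
    seed: int = 0
    subsample_n: int = 33
    iterations: int = 1000
    mef_table: ExpansionFactorTable | None = None
    sef_table: ExpansionFactorTable | None = None
    trunk_fractions: tuple[float, ...] = (0.9, 0.8, 0.7)
    circumference_units: str = "mm"

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if any(not 0 < f <= 1 for f in self.trunk_fractions):
            raise ValueError(f"trunk fractions must be in (0, 1]: {self.trunk_fractions}")
        if self.circumference_units != "mm":
            raise ValueError(
                "stylopodial circumferences must be in millimetres to match the "
                f"predictive equation; got units {self.circumference_units!r}"
            )

    def config_hash(self) -> str:
        payload = {
            "density": self.density,
            "seed": self.seed,
            "subsample_n": self.subsample_n,
            "iterations": self.iterations,
            "trunk_fractions": list(self.trunk_fractions),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _parse_value(raw) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    return float(raw)


def load_specimen_table(path: str | Path) -> list[SpecimenRecord]:
    """Read and validate a specimen CSV.

    Raises :class:`SpecimenTableError` naming missing columns, or listing
    the 1-based data line numbers (header = line 1) of every row that
    violates an invariant.
    """
    df = pd.read_csv(path)
    missing = _REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise SpecimenTableError(f"{path}: missing required columns {sorted(missing)}")
    records: list[SpecimenRecord] = []
    failures: list[str] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header occupies line 1
        try:
            records.append(
                SpecimenRecord(
                    species=str(row["species"]),
                    clade=str(row["clade"]),
                    known_mass_kg=_parse_value(row.get("known_mass_kg")),
                    mch_volume_m3=_parse_value(row.get("mch_volume_m3")),
                    humerus_circ_mm=_parse_value(row.get("humerus_circ_mm")),
                    femur_circ_mm=_parse_value(row.get("femur_circ_mm")),
                    humerus_len_mm=_parse_value(row.get("humerus_len_mm")),
                    femur_len_mm=_parse_value(row.get("femur_len_mm")),
                    mass_provenance=str(row.get("mass_provenance", "measured"))
                    if not pd.isna(row.get("mass_provenance", "measured"))
                    else "measured",
                )
            )
        except (SpecimenTableError, ValueError) as exc:
            failures.append(f"line {line_no}: {exc}")
    if failures:
        raise SpecimenTableError(f"{path}: {len(failures)} invalid rows\n" + "\n".join(failures))
    logger.info("loaded %d specimen records from %s", len(records), path)
    return records


def records_to_frame(records: list[SpecimenRecord]) -> pd.DataFrame:
    """Specimen records as a DataFrame in the canonical CSV schema."""
    return pd.DataFrame([r.__dict__ for r in records])


def calibrate(
    records: list[SpecimenRecord], density: float = DEFAULT_DENSITY
) -> tuple[ScalingFit, ScalingFit]:
    """Fit the two predictive equations on extant records with known mass.

    * volumetric: log10(mass) ~ log10(hull volume x density)
    * stylopodial: log10(mass) ~ log10(humerus + femur circumference)

    Each fit uses the subset of records carrying the relevant predictor;
    a warning is logged when only one clade is represented.
    """
    vol = [(r.mch_volume_m3 * density, r.known_mass_kg) for r in records
           if r.mch_volume_m3 is not None and r.known_mass_kg is not None]
    circ = [(r.combined_circ_mm, r.known_mass_kg) for r in records
            if r.combined_circ_mm is not None and r.known_mass_kg is not None]
    if len(vol) < 3:
        raise ValueError(f"need >= 3 records with hull volume and known mass, got {len(vol)}")
    if len(circ) < 3:
        raise ValueError(
            f"need >= 3 records with circumference pair and known mass, got {len(circ)}"
        )
    clades = {r.clade for r in records if r.known_mass_kg is not None}
    if len(clades) < 2:
        warnings.warn(
            f"calibration sample covers a single clade ({clades}); the fitted equations "
            "may not generalise across amniotes",
            stacklevel=2,
        )
    mch_fit = fit_loglog(*zip(*vol))
    ss_fit = fit_loglog(*zip(*circ))
    n_lit = sum(1 for r in records if r.mass_provenance == "literature_scaling")
    if n_lit:
        logger.info("calibration includes %d literature-scaled masses", n_lit)
    return mch_fit, ss_fit


def estimate_fossils(
    records: list[SpecimenRecord],
    mch_fit: ScalingFit,
    ss_fit: ScalingFit,
    density: float = DEFAULT_DENSITY,
) -> list[FossilEstimateRow]:
    """Predict fossil masses with both methods and rank by their ratio.

    Rows are sorted descending by the stylopodial/volumetric mass ratio;
    taxa missing one predictor get that estimate (and the ratio) marked
    unavailable and sort last.
    """
    rows: list[FossilEstimateRow] = []
    for rec in records:
        mch_kg = (
            predict_mass_mch(rec.mch_volume_m3, density=density, fit=mch_fit)
            if rec.mch_volume_m3 is not None
            else None
        )
        ss_kg = (
            predict_mass_ss(rec.humerus_circ_mm, rec.femur_circ_mm, fit=ss_fit)
            if rec.combined_circ_mm is not None
            else None
        )
        ratio = ss_kg / mch_kg if (mch_kg is not None and ss_kg is not None) else None
        rows.append(
            FossilEstimateRow(
                species=rec.species,
                log10_mch=math.log10(mch_kg) if mch_kg is not None else None,
                mch_kg=mch_kg,
                log10_ss=math.log10(ss_kg) if ss_kg is not None else None,
                ss_kg=ss_kg,
                ratio_ss_mch=ratio,
            )
        )
    return sorted(rows, key=lambda r: (r.ratio_ss_mch is None, -(r.ratio_ss_mch or 0.0)))


def accuracy_report(
    records: list[SpecimenRecord],
    mch_fit: ScalingFit,
    ss_fit: ScalingFit,
    config: StudyConfig = StudyConfig(),
) -> dict:
    """Per-method, per-group PPE accuracy/precision summary.

    Returns ``{(method, group): PPEReport}`` for method in {"mch", "ss"}
    and group in {"total"} + the clades present, plus key
    ``("ss", "subsampled")`` holding the list of (mean, CI halfwidth)
    pairs from subsampling the stylopodial sample down to the volumetric
    sample size (``config.subsample_n``) for ``config.iterations`` draws.
    """
    per_method: dict[str, list[tuple[str, float, float]]] = {"mch": [], "ss": []}
    for rec in records:
        if rec.known_mass_kg is None:
            continue
        if rec.mch_volume_m3 is not None:
            pred = predict_mass_mch(rec.mch_volume_m3, density=config.density, fit=mch_fit)
            per_method["mch"].append((rec.clade, *ppe(rec.known_mass_kg, pred)))
        if rec.combined_circ_mm is not None:
            pred = predict_mass_ss(rec.humerus_circ_mm, rec.femur_circ_mm, fit=ss_fit)
            per_method["ss"].append((rec.clade, *ppe(rec.known_mass_kg, pred)))

    out: dict = {}
    for method, triples in per_method.items():
        if not triples:
            continue
        groups: dict[str, list[tuple[float, float]]] = {"total": []}
        for clade, abs_ppe, signed_ppe in triples:
            groups["total"].append((abs_ppe, signed_ppe))
            groups.setdefault(clade, []).append((abs_ppe, signed_ppe))
        for group, pairs in groups.items():
            abs_vals = np.array([p[0] for p in pairs])
            signed_vals = np.array([p[1] for p in pairs])
            if len(abs_vals) >= 2:
                mean, half = mean_ppe_ci(abs_vals)
            else:
                mean, half = float(abs_vals.mean()), float("nan")
            out[(method, group)] = PPEReport(
                ppe_values=abs_vals,
                signed_values=signed_vals,
                mean_abs_ppe=mean,
                ci95_halfwidth=half,
                group=group,
            )
    ss_total = out.get(("ss", "total"))
    if ss_total is not None and config.subsample_n <= len(ss_total.ppe_values):
        out[("ss", "subsampled")] = subsample_mean_ppe(
            ss_total.ppe_values,
            subsample_n=config.subsample_n,
            iterations=config.iterations,
            seed=config.seed,
        )
    return out


def method_discrepancy_fit(rows: list[FossilEstimateRow]) -> ScalingFit:
    """Regress log10 stylopodial-estimated on log10 volumetric-estimated mass.

    A slope above 1 means the discrepancy between the two estimation
    methods grows with body size.
    """
    pairs = [(r.mch_kg, r.ss_kg) for r in rows if r.mch_kg is not None and r.ss_kg is not None]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 fossils with both estimates, got {len(pairs)}")
    return fit_loglog(*zip(*pairs))


def published_fossil_rows() -> list[FossilEstimateRow]:
    """The published fossil mass table as estimate rows.

    The ratio column is recomputed from the printed mass columns rather
    than copied, so downstream consistency checks exercise real division.
    """
    rows = [
        FossilEstimateRow(
            species=name,
            log10_mch=log_mch,
            mch_kg=mch_kg,
            log10_ss=log_ss,
            ss_kg=ss_kg,
            ratio_ss_mch=ss_kg / mch_kg,
        )
        for name, log_mch, mch_kg, log_ss, ss_kg, _ in FOSSIL_MASS_TABLE
    ]
    return rows


def write_fossil_table(rows: list[FossilEstimateRow], path: str | Path) -> None:
    """Write fossil estimates as CSV (ratio at 1 decimal, masses full precision)."""
    frame = pd.DataFrame(
        [
            {
                "species": r.species,
                "log10_mch": r.log10_mch,
                "mch_kg": r.mch_kg,
                "log10_ss": r.log10_ss,
                "ss_kg": r.ss_kg,
                "ratio": r.rounded_ratio(),
            }
            for r in rows
        ]
    )
    frame.to_csv(path, index=False)


def com_study(models: list[BodyModel], config: StudyConfig = StudyConfig()) -> pd.DataFrame:
    """Regress CoM positional proxies on log10 skull:tail ratio per group.

    For each variant — ``MCH`` (bare hulls), ``MEF``/``SEF`` (expanded,
    when tables are configured; mammals get MEF, crocodylians SEF, fossils
    both), and ``trunk90/80/70`` — and each clade with >= 3 usable models,
    fits ``pct_AG`` and ``dca_fl`` against the log10 skull:tail volume
    ratio.  The ``significant`` column applies the p < 0.05 reporting
    gate (two-sided slope t-test, no multiple-testing correction).
    """
    variants: list[tuple[str, str | None]] = [("MCH", None)]
    if config.mef_table is not None:
        variants.append(("MEF", "mef"))
    if config.sef_table is not None:
        variants.append(("SEF", "sef"))
    for frac in config.trunk_fractions:
        variants.append((f"trunk{int(round(frac * 100))}", f"deflate:{frac}"))

    records = []
    for variant, action in variants:
        for model in models:
            if model.landmarks is None:
                continue
            if action == "mef":
                if model.clade == "crocodylian":
                    continue  # crocodylians are expanded with SEFs only
                varied = apply_expansion(model, config.mef_table)
            elif action == "sef":
                if model.clade == "mammal":
                    continue  # mammals are expanded with MEFs only
                varied = apply_expansion(model, config.sef_table)
            elif action and action.startswith("deflate:"):
                varied = deflate_trunk(model, float(action.split(":")[1]))
            else:
                varied = model
            metrics = com_metrics(varied)
            if metrics.log10_skull_tail is None:
                continue  # tailless or skull-less: excluded from the ratio analysis
            records.append(
                {
                    "specimen": model.specimen,
                    "group": model.clade,
                    "variant": variant,
                    "log10_skull_tail": metrics.log10_skull_tail,
                    "pct_AG": metrics.pct_AG,
                    "dca_fl": metrics.dca_fl,
                }
            )
    data = pd.DataFrame(records)

    rows = []
    if data.empty:
        return pd.DataFrame(rows)
    for (group, variant), chunk in data.groupby(["group", "variant"], sort=False):
        if len(chunk) < 3:
            warnings.warn(
                f"CoM study: group {group!r} variant {variant!r} has n={len(chunk)} < 3; skipped",
                stacklevel=2,
            )
            continue
        for metric in ("pct_AG", "dca_fl"):
            x = 10.0 ** chunk["log10_skull_tail"].to_numpy()  # fit_loglog re-logs
            y = chunk[metric].to_numpy()
            if np.allclose(y, y[0]) or np.allclose(x, x[0]):
                rows.append(
                    {
                        "group": group, "variant": variant, "metric": metric,
                        "n": len(chunk), "p": 1.0, "r2": 0.0, "slope": 0.0,
                        "slope_ci_lo": np.nan, "slope_ci_hi": np.nan,
                        "intercept": float(np.mean(y)),
                        "intercept_ci_lo": np.nan, "intercept_ci_hi": np.nan,
                        "significant": False,
                    }
                )
                continue
            # Plain OLS of the metric on log10 skull:tail (metric may be
            # negative, so no log transform on the response).
            lx = np.log10(x)
            res = sm.OLS(y, sm.add_constant(lx)).fit()
            ci = res.conf_int(alpha=0.05)
            rows.append(
                {
                    "group": group, "variant": variant, "metric": metric,
                    "n": len(chunk),
                    "p": float(res.pvalues[1]),
                    "r2": float(res.rsquared),
                    "slope": float(res.params[1]),
                    "slope_ci_lo": float(ci[1, 0]),
                    "slope_ci_hi": float(ci[1, 1]),
                    "intercept": float(res.params[0]),
                    "intercept_ci_lo": float(ci[0, 0]),
                    "intercept_ci_hi": float(ci[0, 1]),
                    "significant": bool(res.pvalues[1] < 0.05),
                }
            )
    return pd.DataFrame(rows)
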