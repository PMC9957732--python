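"""Classification of pottery organic residues from molecular and isotopic features.

Each analysed residue (an absorbed sherd extract or a charred surface
deposit, "foodcrust") carries a set of GC–MS / GC–C–IRMS derived features:
lipid concentration, compound-specific carbon isotope values of palmitic
(C16:0) and stearic (C18:0) acid, and presence flags or ratios for
diagnostic biomarkers (APAAs, isoprenoid acids, sterols, waxes...).

Seventeen interpretative criteria map these features onto food commodity
classes:

* aquatic resources — APAA chain-length pattern plus isoprenoid acids (c1),
  the C20:C18 APAA ratio (c2), or the SRR phytanic-acid diastereomer
  percentage (c3);
* ruminant fats — Δ¹³C = δ¹³C(C18:0) − δ¹³C(C16:0) below −1.72‰ (c4), or a
  milder Δ¹³C cut combined with a low SRR% (c5);
* non-specific animal fat — cholesterol alteration products, unless any of
  c2–c5 already identifies the fat (c6);
* plant resources — epicuticular-wax alkanes/acids, fatty-acid ratios,
  terpenoids, sterols, the APAA-C18 E:H isomer ratio or 2-hydroxy acids
  (c7–c14);
* heating — APAAs, long-chain ketones or benzene polycarboxylic acids
  (c15–c17).

Criteria evaluate to a three-valued {true, false, unknown} logic: a missing
measurement gives *unknown*, and unknowns are treated as false when classes
are assigned, so the class counts are a conservative minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import SiteRecord, TraitMatrix, USE_BLOCK, logger

UNKNOWN = None  # three-valued logic: True / False / None


@dataclass(frozen=True)
class ReferenceFatStats:
    """Δ¹³C reference statistics (‰) for modern fats from the study area."""

    ruminant_mean: float = -2.28
    ruminant_sd: float = 1.02
    ruminant_n: int = 39
    nonruminant_mean: float = 0.36
    nonruminant_sd: float = 1.04
    nonruminant_n: int = 345


@dataclass(frozen=True)
class CriteriaThresholds:
    """Decision thresholds for the 17 criteria; defaults are the published cuts.

    ``ruminant_delta13c`` is the non-ruminant mean minus two of its standard
    deviations (0.36 − 2×1.04 = −1.72‰).
    """

    apaa_c20_c18_ratio: float = 0.06        # c2, unitless
    srr_aquatic_pct: float = 75.5           # c3, %
    ruminant_delta13c: float = -1.72        # c4, ‰
    ruminant_delta13c_relaxed: float = -1.26  # c5, ‰
    ruminant_srr_max_pct: float = 64.0      # c5, %
    lcsfa_pct: float = 15.0                 # c8, % of saturated fatty acids
    ps_ratio: float = 4.0                   # c9, C16:0/C18:0
    c12_c14_ratio: float = 1.0              # c10
    apaa_e_h_ratio: float = 4.0             # c13
    conc_sherd: float = 5.0                 # interpretability gate, µg g⁻¹
    conc_foodcrust: float = 100.0           # interpretability gate, µg g⁻¹

    @classmethod
    def from_reference(cls, ref: ReferenceFatStats = ReferenceFatStats(), **overrides):
        """Derive the Δ¹³C cut-offs from reference fat statistics."""
        # report at the 2-decimal precision of the reference statistics
        return cls(
            ruminant_delta13c=round(ref.nonruminant_mean - 2 * ref.nonruminant_sd, 2),
            ruminant_delta13c_relaxed=round(ref.ruminant_mean + ref.ruminant_sd, 2),
            **overrides,
        )


DEFAULT_THRESHOLDS = CriteriaThresholds()


@dataclass
class LipidSample:
    """One analysed residue with measured molecular/isotopic features.

    Every analytical field is optional; missing measurements propagate as
    *unknown* through criterion evaluation.  Units: ``lipid_conc`` µg g⁻¹,
    isotope values ‰ VPDB, ``srr_pct``/``lcsfa_pct`` percent, ratios unitless.
    """

    sample_id: str
    vessel_id: str = ""
    site_id: str = ""
    sample_type: str = "sherd"  # sherd | foodcrust
    lipid_conc: Optional[float] = None
    d13c_16_0: Optional[float] = None
    d13c_18_0: Optional[float] = None
    delta13c: Optional[float] = None
    apaa_c18: Optional[bool] = None
    apaa_c20: Optional[bool] = None
    apaa_c22: Optional[bool] = None
    apaa_c20_c18_ratio: Optional[float] = None
    phytanic: Optional[bool] = None
    pristanic: Optional[bool] = None
    tmtd: Optional[bool] = None
    srr_pct: Optional[float] = None
    chol_deriv: Optional[bool] = None
    alkane_odd_dominance: Optional[bool] = None
    lcsfa_pct: Optional[float] = None
    ps_ratio: Optional[float] = None
    c12_c14_ratio: Optional[float] = None
    amyrins: Optional[bool] = None
    phytosterols: Optional[bool] = None
    apaa_e_h_ratio: Optional[float] = None
    hydroxy_fa: Optional[bool] = None
    lc_ketones: Optional[bool] = None
    bpca: Optional[bool] = None
    terpenoid_profile: Optional[bool] = None
    beeswax: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.sample_type not in ("sherd", "foodcrust"):
            raise ValueError(
                f"sample {self.sample_id}: unknown sample_type {self.sample_type!r}"
            )
        if self.lipid_conc is not None and self.lipid_conc < 0:
            raise ValueError(f"sample {self.sample_id}: negative lipid concentration")
        for name in ("srr_pct", "lcsfa_pct"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise ValueError(f"sample {self.sample_id}: {name}={v} outside [0, 100]")
        # Δ¹³C is defined as δ¹³C(C18:0) − δ¹³C(C16:0); recompute or cross-check.
        if self.d13c_16_0 is not None and self.d13c_18_0 is not None:
            implied = self.d13c_18_0 - self.d13c_16_0
            if self.delta13c is None:
                self.delta13c = implied
            elif abs(self.delta13c - implied) > 0.05:
                raise ValueError(
                    f"sample {self.sample_id}: delta13c {self.delta13c} inconsistent "
                    f"with d13c_18_0 - d13c_16_0 = {implied:.3f}"
                )


#: Flags whose presence alone ties a residue to a specific source, letting a
#: low-yield sample pass the interpretability gate.
DISTINCTIVE_FLAGS = (
    "apaa_c18", "apaa_c20", "apaa_c22", "phytanic", "pristanic", "tmtd",
    "chol_deriv", "alkane_odd_dominance", "amyrins", "phytosterols",
    "hydroxy_fa", "lc_ketones", "terpenoid_profile", "beeswax",
)

CRITERION_IDS = tuple(f"c{i}" for i in range(1, 18))


@dataclass(frozen=True)
class CriterionVector:
    """Three-valued outcome of the 17 criteria for one sample."""

    c1: Optional[bool] = None
    c2: Optional[bool] = None
    c3: Optional[bool] = None
    c4: Optional[bool] = None
    c5: Optional[bool] = None
    c6: Optional[bool] = None
    c7: Optional[bool] = None
    c8: Optional[bool] = None
    c9: Optional[bool] = None
    c10: Optional[bool] = None
    c11: Optional[bool] = None
    c12: Optional[bool] = None
    c13: Optional[bool] = None
    c14: Optional[bool] = None
    c15: Optional[bool] = None
    c16: Optional[bool] = None
    c17: Optional[bool] = None

    def as_dict(self) -> dict[str, Optional[bool]]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass(frozen=True)
class ResidueAssignment:
    """Commodity classes and heating inferred for one sample."""

    interpretable: bool = True
    aquatic: bool = False
    ruminant: bool = False
    animal_nonspecific: bool = False
    plant: bool = False
    heating: bool = False

    CLASSES = ("aquatic", "ruminant", "animal_nonspecific", "plant", "heating")


def interpretability_gate(
    sample: LipidSample, thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Whether a sample yields enough lipid (or distinctive biomarkers) to interpret.

    Absorbed sherd residues require > 5 µg g⁻¹ and charred surface deposits
    > 100 µg g⁻¹; a sample under its threshold still passes if any
    source-specific biomarker is present.
    """
    cut = thresholds.conc_sherd if sample.sample_type == "sherd" else thresholds.conc_foodcrust
    if sample.lipid_conc is not None and sample.lipid_conc > cut:
        return True
    return any(bool(getattr(sample, f)) for f in DISTINCTIVE_FLAGS)


def _and3(*vals):
    if any(v is False for v in vals):
        return False
    if any(v is None for v in vals):
        return UNKNOWN
    return True


def _or3(*vals):
    if any(v is True for v in vals):
        return True
    if any(v is None for v in vals):
        return UNKNOWN
    return False


def _gt(value: Optional[float], cut: float) -> Optional[bool]:
    return UNKNOWN if value is None else bool(value > cut)


def _lt(value: Optional[float], cut: float) -> Optional[bool]:
    return UNKNOWN if value is None else bool(value < cut)


def evaluate_criteria(
    sample: LipidSample, thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS
) -> CriterionVector:
    """Evaluate the 17 interpretative criteria on one sample.

    Missing inputs yield *unknown* for the criteria that need them; presence
    flags left unset are likewise unknown (absence of evidence is not recorded
    evidence of absence at the feature level).
    """
    t = thresholds
    s = sample
    c1 = _and3(s.apaa_c18, _or3(s.apaa_c20, s.apaa_c22), _or3(s.phytanic, s.pristanic, s.tmtd))
    cv = CriterionVector(
        c1=c1,
        c2=_gt(s.apaa_c20_c18_ratio, t.apaa_c20_c18_ratio),
        c3=_gt(s.srr_pct, t.srr_aquatic_pct),
        c4=_lt(s.delta13c, t.ruminant_delta13c),
        c5=_and3(_lt(s.delta13c, t.ruminant_delta13c_relaxed),
                 _lt(s.srr_pct, t.ruminant_srr_max_pct)),
        c6=s.chol_deriv,
        c7=s.alkane_odd_dominance,
        c8=_gt(s.lcsfa_pct, t.lcsfa_pct),
        c9=_gt(s.ps_ratio, t.ps_ratio),
        c10=_gt(s.c12_c14_ratio, t.c12_c14_ratio),
        c11=s.amyrins,
        c12=s.phytosterols,
        c13=_gt(s.apaa_e_h_ratio, t.apaa_e_h_ratio),
        c14=s.hydroxy_fa,
        c15=_or3(s.apaa_c18, s.apaa_c20, s.apaa_c22),
        c16=s.lc_ketones,
        c17=s.bpca,
    )
    return cv


def assign_classes(cv: CriterionVector, interpretable: bool = True) -> ResidueAssignment:
    """Combine criteria into commodity classes.

    aquatic = (c1 AND c2) OR c3; ruminant = c4 OR c5; non-specific animal =
    c6 AND NOT (c2..c5); plant = any of c7..c14; heating = any of c15..c17.
    Unknown criteria count as false, so assignments are a conservative floor.
    """
    d = {k: bool(v) for k, v in cv.as_dict().items()}  # unknown -> False
    return ResidueAssignment(
        interpretable=interpretable,
        aquatic=(d["c1"] and d["c2"]) or d["c3"],
        ruminant=d["c4"] or d["c5"],
        animal_nonspecific=d["c6"] and not (d["c2"] or d["c3"] or d["c4"] or d["c5"]),
        plant=any(d[f"c{i}"] for i in range(7, 15)),
        heating=any(d[f"c{i}"] for i in range(15, 18)),
    )


def classify_sample(
    sample: LipidSample, thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS
) -> tuple[CriterionVector, ResidueAssignment]:
    cv = evaluate_criteria(sample, thresholds)
    gate = interpretability_gate(sample, thresholds)
    assign = assign_classes(cv, interpretable=gate)
    if not gate:
        assign = ResidueAssignment(interpretable=False)
    return cv, assign


_BOOL_FIELDS = {
    f.name for f in dc_fields(LipidSample)
    if f.type == "Optional[bool]"
}


def samples_from_frame(df: pd.DataFrame) -> list[LipidSample]:
    """Build :class:`LipidSample` objects from a lipid CSV table."""
    known = {f.name for f in dc_fields(LipidSample)}
    extra = set(df.columns) - known
    if extra:
        logger.info("lipid table: ignoring unknown columns %s", sorted(extra))
    out = []
    for _, row in df.iterrows():
        kw = {}
        for name in known & set(df.columns):
            v = row[name]
            if pd.isna(v):
                continue
            if name in _BOOL_FIELDS:
                kw[name] = bool(v) if not isinstance(v, str) else v.strip().lower() in ("1", "true", "yes")
            elif name in ("sample_id", "vessel_id", "site_id", "sample_type"):
                kw[name] = str(v)
            else:
                kw[name] = float(v)
        out.append(LipidSample(**kw))
    return out


def classify_table(
    lipids: pd.DataFrame | Sequence[LipidSample],
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Classify a whole table; returns ids + c1..c17 (1/0/NA) + class booleans.

    Also logs an audit of how often unknown criteria may have suppressed a
    class (conservative-counting audit).
    """
    samples = samples_from_frame(lipids) if isinstance(lipids, pd.DataFrame) else list(lipids)
    rows = []
    n_unknown_suppressions = 0
    for s in samples:
        cv, a = classify_sample(s, thresholds)
        d = cv.as_dict()
        n_unknown = sum(v is None for v in d.values())
        if n_unknown and not all(
            getattr(a, c) for c in ResidueAssignment.CLASSES
        ):
            n_unknown_suppressions += 1
        rec = {"sample_id": s.sample_id, "vessel_id": s.vessel_id, "site_id": s.site_id,
               "sample_type": s.sample_type, "interpretable": a.interpretable}
        rec.update({k: (np.nan if v is None else int(v)) for k, v in d.items()})
        rec.update({c: getattr(a, c) for c in ResidueAssignment.CLASSES})
        rec["n_unknown_criteria"] = n_unknown
        rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out):
        logger.info(
            "classified %d samples; %d interpretable; %d with unknown criteria that "
            "could only have added classes (conservative floor)",
            len(out), int(out["interpretable"].sum()), n_unknown_suppressions,
        )
    return out


def summarize_by_region(
    classified: pd.DataFrame, sites: Sequence[SiteRecord]
) -> pd.DataFrame:
    """Per-region relative frequency of each commodity class.

    Fractions are over *interpretable* samples in the region; each detected
    product counts once per sample, and absorbed/foodcrust residues from one
    vessel are separate cases (they are separate samples).
    """
    region_of = {s.site_id: s.region for s in sites}
    missing = sorted(set(classified["site_id"]) - set(region_of))
    if missing:
        raise ValueError(f"samples from sites without region metadata: {missing[:5]}")
    df = classified.copy()
    df["region"] = df["site_id"].map(region_of)
    rows = []
    for region, grp in df.groupby("region"):
        interp = grp[grp["interpretable"]]
        n = len(interp)
        if n == 0:
            raise ValueError(f"region {region!r} has no interpretable samples")
        for cls in ResidueAssignment.CLASSES:
            count = int(interp[cls].sum())
            rows.append({"region": region, "class": cls, "n_interpretable": n,
                         "count": count, "fraction": count / n})
    return pd.DataFrame(rows)


def residue_trait_matrix(classified: pd.DataFrame) -> TraitMatrix:
    """Vessel-level use-trait matrix (block 'use') from classifier output.

    A vessel presents a use trait if any of its interpretable samples does.
    Row ids are ``site:vessel`` so site aggregation can recover the site id.
    """
    interp = classified[classified["interpretable"]]
    if interp.empty:
        raise ValueError("no interpretable samples")
    cols = list(ResidueAssignment.CLASSES)
    agg = interp.groupby(["site_id", "vessel_id"])[cols].any().astype(int)
    row_ids = [f"{s}:{v}" for s, v in agg.index]
    return TraitMatrix(
        row_ids, [f"use_{c}" for c in cols], [USE_BLOCK] * len(cols),
        agg.to_numpy(), level="vessel",
    )
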