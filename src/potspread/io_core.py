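"""Shared data model, file formats, configuration and the pipeline driver.

The pipeline moves four kinds of object between stages:

* :class:`SiteRecord` — an archaeological site with WGS84 coordinates, a
  region label and a vector of posterior draws for the local arrival date of
  pottery, in years cal BC (larger = earlier).
* :class:`TraitMatrix` — binary presence/absence of pottery traits at vessel
  or site level, each trait tagged with a block (decoration, morphology,
  technology or use).
* :class:`DistanceMatrix` — a labelled symmetric dissimilarity matrix
  (Jaccard, great-circle, least-cost, resistance or temporal).
* :class:`CostRaster` — a projected cost/elevation grid carried in the ESRI
  ASCII grid text format.

All tabular formats are plain CSV so that every artefact of a run is
inspectable with a text editor.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("potspread")

#: Trait blocks describing how a pot was made.
PRODUCTION_BLOCKS = ("decoration", "morphology", "technology")
#: Trait block describing what a pot was used for (organic-residue traits).
USE_BLOCK = "use"
VALID_BLOCKS = PRODUCTION_BLOCKS + (USE_BLOCK,)

NODATA_DEFAULT = -9999.0


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a console handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SiteRecord:
    """One site: location, region and arrival-date posterior draws (cal BC)."""

    site_id: str
    lon: float
    lat: float
    region: str
    date_posterior: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"site {self.site_id}: latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"site {self.site_id}: longitude {self.lon} outside [-180, 180]")
        self.date_posterior = np.asarray(self.date_posterior, dtype=float)


class TraitMatrix:
    """Binary presence/absence of traits, tagged by block, at vessel or site level."""

    def __init__(
        self,
        row_ids: Sequence[str],
        trait_ids: Sequence[str],
        blocks: Sequence[str],
        values: np.ndarray,
        level: str = "vessel",
    ) -> None:
        values = np.asarray(values)
        if values.shape != (len(row_ids), len(trait_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(row_ids)} rows x {len(trait_ids)} traits"
            )
        if len(blocks) != len(trait_ids):
            raise ValueError("one block tag per trait required")
        bad_blocks = sorted(set(blocks) - set(VALID_BLOCKS))
        if bad_blocks:
            raise ValueError(f"unknown trait block(s): {bad_blocks}; expected {VALID_BLOCKS}")
        if len(set(row_ids)) != len(row_ids):
            raise ValueError("duplicate row ids")
        if len(set(trait_ids)) != len(trait_ids):
            raise ValueError("duplicate trait ids")
        if values.size == 0:
            raise ValueError("empty trait matrix")
        if not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValueError(
                f"non-binary cell at row {row_ids[bad[0]]!r}, trait {trait_ids[bad[1]]!r}: "
                f"{values[bad[0], bad[1]]!r}"
            )
        if level not in ("vessel", "site"):
            raise ValueError(f"level must be 'vessel' or 'site', got {level!r}")
        self.row_ids = list(map(str, row_ids))
        self.trait_ids = list(map(str, trait_ids))
        self.blocks = list(blocks)
        self.values = values.astype(np.int8)
        self.level = level

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def block_counts(self) -> dict[str, int]:
        """Number of traits per block, in canonical block order."""
        return {b: self.blocks.count(b) for b in VALID_BLOCKS if b in self.blocks}

    def select_blocks(self, blocks: Iterable[str]) -> "TraitMatrix":
        """Column subset restricted to the given blocks (order preserved)."""
        wanted = set(blocks)
        bad = sorted(wanted - set(VALID_BLOCKS))
        if bad:
            raise ValueError(f"unknown block(s) {bad}")
        cols = [j for j, b in enumerate(self.blocks) if b in wanted]
        if not cols:
            raise ValueError(f"no traits in blocks {sorted(wanted)}")
        return TraitMatrix(
            self.row_ids,
            [self.trait_ids[j] for j in cols],
            [self.blocks[j] for j in cols],
            self.values[:, cols],
            level=self.level,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.trait_ids)


class DistanceMatrix:
    """Labelled symmetric nonnegative dissimilarity matrix with zero diagonal."""

    def __init__(self, labels: Sequence[str], values: np.ndarray, metric_name: str = "distance"):
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} labels")
        if len(set(labels)) != n:
            raise ValueError("duplicate labels")
        if np.isnan(values).any():
            raise ValueError("NaN distances")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-10):
            raise ValueError("nonzero diagonal")
        if (values < -1e-12).any():
            raise ValueError("negative distances")
        self.labels = list(map(str, labels))
        self.values = 0.5 * (values + values.T)
        np.fill_diagonal(self.values, 0.0)
        self.metric_name = metric_name

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle (row-major upper triangle) vector of off-diagonal values."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def align_to(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Reorder/subset to the given label sequence."""
        idx = []
        pos = {lab: i for i, lab in enumerate(self.labels)}
        for lab in labels:
            if lab not in pos:
                raise KeyError(f"label {lab!r} not in distance matrix")
            idx.append(pos[lab])
        idx = np.asarray(idx)
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.metric_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class CostRaster:
    """Projected grid of per-cell traversal costs (or elevations), metres units.

    ``values[0, 0]`` is the north-west (top-left) cell, matching the ESRI
    ASCII grid layout; ``(xll, yll)`` is the lower-left corner of the grid.
    NaN cells are nodata (non-traversable).
    """

    xll: float
    yll: float
    cellsize: float
    values: np.ndarray
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        # positivity of costs is validated by the consumers that require it
        # (a DEM carried in the same container may legitimately hold zeros)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Projected (x, y) of a cell centre; row 0 is the top row."""
        x = self.xll + (col + 0.5) * self.cellsize
        y = self.yll + (self.n_rows - row - 0.5) * self.cellsize
        return x, y

    def nearest_cell(self, x: float, y: float) -> tuple[int, int]:
        col = int(np.clip(np.floor((x - self.xll) / self.cellsize), 0, self.n_cols - 1))
        row_from_bottom = int(np.clip(np.floor((y - self.yll) / self.cellsize), 0, self.n_rows - 1))
        return self.n_rows - 1 - row_from_bottom, col


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_trait_table(
    path: str | Path,
    level: str = "vessel",
    blocks: Mapping[str, str] | None = None,
) -> TraitMatrix:
    """Read a binary trait table from CSV.

    Layout: header row of trait ids (first column holds row ids); an optional
    second row whose first cell is ``block`` carrying the per-trait block tag;
    then one data row per vessel/site.  When the block row is absent a
    ``blocks`` mapping (trait id -> block tag) must be supplied.  NA cells are
    treated as absence; the count of NAs is logged so the user can judge the
    impact.
    """
    df = pd.read_csv(path, index_col=0, dtype=object)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"empty trait table: {path}")
    if df.index[0] == "block":
        block_tags = [str(v) for v in df.iloc[0]]
        df = df.iloc[1:]
    elif blocks is not None:
        missing = [t for t in df.columns if t not in blocks]
        if missing:
            raise ValueError(f"traits without block tag: {missing[:5]}")
        block_tags = [blocks[t] for t in df.columns]
    else:
        raise ValueError(f"{path}: no 'block' row and no block mapping supplied")
    raw = df.to_numpy()
    n_missing = int(pd.isna(raw).sum())
    if n_missing:
        frac = n_missing / raw.size
        logger.info(
            "trait table %s: %d missing cells (%.1f%%) treated as absence",
            path, n_missing, 100 * frac,
        )
    vals = np.zeros(raw.shape, dtype=np.int8)
    for (i, j), v in np.ndenumerate(raw):
        if pd.isna(v):
            continue
        s = str(v).strip()
        if s in ("0", "0.0"):
            vals[i, j] = 0
        elif s in ("1", "1.0"):
            vals[i, j] = 1
        else:
            raise ValueError(
                f"{path}: non-binary value {v!r} at row {df.index[i]!r}, trait {df.columns[j]!r}"
            )
    tm = TraitMatrix(list(df.index), list(df.columns), block_tags, vals, level=level)
    logger.info("trait table %s: %s rows, block counts %s", path, tm.shape[0], tm.block_counts())
    return tm


def write_trait_table(tm: TraitMatrix, path: str | Path) -> None:
    """Write a trait table in the layout understood by :func:`read_trait_table`."""
    with open(path, "w") as fh:
        fh.write("id," + ",".join(tm.trait_ids) + "\n")
        fh.write("block," + ",".join(tm.blocks) + "\n")
        for rid, row in zip(tm.row_ids, tm.values):
            fh.write(rid + "," + ",".join(str(int(v)) for v in row) + "\n")


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read site metadata with wide posterior-draw columns ``draw_*``."""
    df = pd.read_csv(path)
    required = {"site_id", "lon", "lat", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    draw_cols = [c for c in df.columns if c.startswith("draw_")]
    sites = []
    for _, row in df.iterrows():
        draws = row[draw_cols].to_numpy(dtype=float) if draw_cols else np.empty(0)
        draws = draws[np.isfinite(draws)]
        sites.append(
            SiteRecord(str(row["site_id"]), float(row["lon"]), float(row["lat"]),
                       str(row["region"]), draws)
        )
    if not sites:
        raise ValueError(f"no sites in {path}")
    return sites


def write_site_table(sites: Sequence[SiteRecord], path: str | Path) -> None:
    n_draws = max((s.date_posterior.size for s in sites), default=0)
    rows = []
    for s in sites:
        rec = {"site_id": s.site_id, "lon": s.lon, "lat": s.lat, "region": s.region}
        for k in range(n_draws):
            rec[f"draw_{k:04d}"] = s.date_posterior[k] if k < s.date_posterior.size else np.nan
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_distance_csv(path: str | Path, metric_name: str | None = None) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    name = metric_name or Path(path).stem
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float), name)


def write_distance_csv(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_frame().to_csv(path, float_format="%.12g")


def write_phylip_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP square distance matrix (interchange with splits/phylogeny tools)."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for lab, row in zip(dm.labels, dm.values):
            safe = lab.replace(" ", "_")[:32]
            fh.write(safe + "  " + "  ".join(f"{v:.10g}" for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> CostRaster:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            "xllcenter", "yllcenter",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {key}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # centre-registered grid
        xll = header["xllcenter"] - cellsize / 2
        yll = header["yllcenter"] - cellsize / 2
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    body = "".join(lines[i:])
    vals = np.loadtxt(io.StringIO(body)).reshape(nrows, ncols)
    vals[vals == nodata] = np.nan
    return CostRaster(xll, yll, cellsize, vals, nodata=nodata)


def write_ascii_grid(raster: CostRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid that round-trips bit-identically via the reader.

    Values are serialized with ``repr``-exact ``%.17g`` so a read-back grid is
    numerically identical.
    """
    vals = raster.values
    out = np.where(np.isfinite(vals), vals, raster.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.xll:.17g}\n")
        fh.write(f"yllcorner {raster.yll:.17g}\n")
        fh.write(f"cellsize {raster.cellsize:.17g}\n")
        fh.write(f"nodata_value {raster.nodata:.17g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Packaged trait dictionary
# ---------------------------------------------------------------------------


def load_trait_dictionary() -> pd.DataFrame:
    """The packaged pottery trait dictionary.

    Schematic trait ids (synthetic placeholders for the published inventory)
    tagged by block — 61 decoration, 61 morphology and 40 technology traits —
    with an ``in_analysis`` flag marking the 129-trait subset used for the
    combined production+use contingency analyses.
    """
    with resources.files("potspread.data").joinpath("trait_dictionary.csv").open() as fh:
        return pd.read_csv(fh)


def trait_dictionary_counts() -> dict[str, dict[str, int]]:
    """Raw and analysis-subset trait counts per block."""
    d = load_trait_dictionary()
    raw = d.groupby("block")["trait_id"].count().to_dict()
    sub = d[d["in_analysis"]].groupby("block")["trait_id"].count().to_dict()
    return {"raw": raw, "analysis_subset": sub}


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

KNOWN_STAGES = (
    "simulate", "classify", "traits", "distances", "ca",
    "mantel", "correlogram", "diffusion", "nnet",
)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def run_pipeline(config: str | Path | Mapping, out_dir: str | Path | None = None) -> Path:
    """Run the staged analysis described by a YAML config; return the run directory.

    Stages execute in the canonical order ``simulate -> classify -> traits ->
    distances -> ca -> mantel -> correlogram -> diffusion -> nnet``; each stage
    writes its outputs into the run directory and contributes to
    ``summary.json``.  Deterministic given ``seed``.
    """
    # imports here to avoid circular imports at module load
    from . import chronology_diffusion, mantel_stats, ordination, residue_criteria
    from . import landscape, splits_network, synthetic_data, trait_distance

    cfg = dict(load_config(config)) if isinstance(config, (str, Path)) else dict(config)
    stages = cfg.get("stages", list(KNOWN_STAGES))
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; known: {KNOWN_STAGES}")
    stages = [s for s in KNOWN_STAGES if s in stages]
    seed = int(cfg.get("seed", 0))
    run_dir = Path(out_dir or cfg.get("out_dir", "potspread_run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    configure_logging()
    log_path = run_dir / "run.log"
    file_handler = logging.FileHandler(log_path, mode="w")
    file_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(file_handler)

    summary: dict = {"seed": seed, "stages": stages}
    sites: list[SiteRecord] | None = None
    traits: TraitMatrix | None = None
    lipids: pd.DataFrame | None = None
    truth = None

    try:
        if "simulate" in stages:
            sim_params = dict(cfg.get("simulate", {}))
            sim_params["seed"] = seed
            sim_cfg = synthetic_data.SimConfig(**sim_params)
            sites, truth = synthetic_data.simulate_sites(sim_cfg)
            traits = synthetic_data.simulate_traits(sites, sim_cfg, truth=truth)
            lipids, truth = synthetic_data.simulate_lipids(sites, sim_cfg, truth=truth)
            write_site_table(sites, run_dir / "sites.csv")
            write_trait_table(traits, run_dir / "traits.csv")
            lipids.to_csv(run_dir / "lipids.csv", index=False)
            with open(run_dir / "truth.json", "w") as fh:
                json.dump(truth.to_jsonable(), fh, indent=1)
            summary["n_sites"] = len(sites)
        else:
            if "sites" in cfg:
                sites = read_site_table(cfg["sites"])
            if "traits" in cfg:
                traits = read_trait_table(cfg["traits"], level=cfg.get("trait_level", "vessel"))
            if "lipids" in cfg:
                lipids = pd.read_csv(cfg["lipids"])

        if "classify" in stages:
            if lipids is None:
                raise ValueError("classify stage requires lipid samples (simulate or 'lipids')")
            classified = residue_criteria.classify_table(lipids)
            classified.to_csv(run_dir / "residue_classes.csv", index=False)
            if sites is not None:
                freq = residue_criteria.summarize_by_region(classified, sites)
                freq.to_csv(run_dir / "residue_by_region.csv", index=False)
            use_traits = residue_criteria.residue_trait_matrix(classified)
            write_trait_table(use_traits, run_dir / "use_traits_vessel.csv")
            summary["n_classified"] = int(len(classified))

        site_traits = None
        jaccard: DistanceMatrix | None = None
        if "traits" in stages:
            if traits is None:
                raise ValueError("traits stage requires a trait matrix")
            site_traits = traits
            if traits.level == "vessel":
                mapping = {r: r.split(":")[0] for r in traits.row_ids}
                site_traits = trait_distance.aggregate(traits, "site", row_to_group=mapping)
            jaccard = trait_distance.jaccard_matrix(site_traits)
            write_distance_csv(jaccard, run_dir / "jaccard_all.csv")
            per_block = {}
            for b in site_traits.block_counts():
                per_block[b] = trait_distance.jaccard_matrix(
                    site_traits, trait_distance.JaccardOptions(blocks=(b,))
                )
                write_distance_csv(per_block[b], run_dir / f"jaccard_{b}.csv")
            block_stats = trait_distance.block_summary(per_block)
            block_stats.to_csv(run_dir / "jaccard_block_summary.csv", index=False)
            summary["jaccard_mean"] = float(np.mean(jaccard.condensed()))

        geo: DistanceMatrix | None = None
        if "distances" in stages:
            if sites is None:
                raise ValueError("distances stage requires a site table")
            geo = landscape.haversine_matrix(sites)
            write_distance_csv(geo, run_dir / "geo_km.csv")

        if "ca" in stages:
            if site_traits is None:
                raise ValueError("ca stage requires site-level traits (run 'traits')")
            ca = ordination.correspondence_analysis(site_traits.to_frame())
            ca.row_scores.to_csv(run_dir / "ca_row_scores.csv")
            summary["ca_inertia_axis1_share"] = float(
                ca.inertia_per_axis[0] / ca.total_inertia
            )

        n_perm = int(cfg.get("n_perm", 499))
        n_boot = int(cfg.get("n_boot", 200))
        if "mantel" in stages:
            if jaccard is None or geo is None:
                raise ValueError("mantel stage requires 'traits' and 'distances' stages")
            res = mantel_stats.mantel(jaccard, geo, n_perm=n_perm, n_boot=n_boot, seed=seed)
            summary["mantel_traits_geo"] = {"r": res.r, "p": res.p_value,
                                            "ci": [res.ci_low, res.ci_high]}

        if "correlogram" in stages:
            if jaccard is None or geo is None:
                raise ValueError("correlogram stage requires 'traits' and 'distances'")
            cg = mantel_stats.mantel_correlogram(jaccard, geo, n_perm=n_perm,
                                                 n_boot=n_boot, seed=seed)
            cg.to_frame().to_csv(run_dir / "correlogram.csv", index=False)

        if "diffusion" in stages:
            if sites is None or geo is None:
                raise ValueError("diffusion stage requires site table and 'distances' stage")
            origin = cfg.get("origin_site", sites[0].site_id)
            fit = chronology_diffusion.diffusion_mc(
                sites, geo, origin_id=origin,
                n_draws=int(cfg.get("n_draws", 200)), seed=seed,
            )
            summary["diffusion"] = {
                "speed_km_per_yr": fit.speed, "ci": [fit.speed_ci_low, fit.speed_ci_high],
                "r": fit.r, "origin": origin,
            }
            with open(run_dir / "diffusion_fit.json", "w") as fh:
                json.dump(summary["diffusion"], fh, indent=1)

        if "nnet" in stages:
            if jaccard is None:
                raise ValueError("nnet stage requires the 'traits' stage")
            net = splits_network.neighbor_net(jaccard)
            splits_network.write_splits_nexus(net, run_dir / "splits.nex")
            summary["nnet"] = {"n_splits": len(net.splits), "fit_residual": net.fit}

        with open(run_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    finally:
        logger.removeHandler(file_handler)
        file_handler.close()
    return run_dir
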