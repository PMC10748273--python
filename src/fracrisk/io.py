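"""Tabular readers/writers, run configuration, and pipeline assembly.

The on-disk format is a plain wide CSV: one row per site, a ``site_id``
column, ``<metal>_total`` columns for total concentrations (mg/kg),
``<metal>_F1`` .. ``<metal>_F4`` columns for the BCR fractions, and
optional soil-property columns (SOM, pH, TN, TP, TK, AN, AP, AK).  A
long-format reader (site_id, metal, variable, value) is offered as well.

``run_pipeline`` chains the stages — descriptive summaries, deterministic
index assessment in classic and/or fraction-modified mode, and the Monte
Carlo propagation — and returns every table as a DataFrame, optionally
writing them (plus a provenance log) under an output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CHINA_BACKGROUND,
    FRACTION_NAMES,
    PROPERTY_NAMES,
    SHAANXI_BACKGROUND,
    STUDY_TOXICITY,
    BackgroundSet,
    FractionVector,
    SiteRecord,
    ToxicityParams,
)
from .descriptive import coefficient_of_variation, exceedance_rate, fraction_profile
from .indices import assess_site, derive_er_scheme, derive_ri_scheme
from .probabilistic import fit_distribution, propagate
from .indices import corrected_concentration

logger = logging.getLogger("fracrisk")

__all__ = [
    "RunConfig",
    "load_run_config",
    "read_sites",
    "read_sites_long",
    "write_sites",
    "run_pipeline",
]


def _metals_in_columns(columns) -> list[str]:
    return sorted({c[: -len("_total")] for c in columns if c.endswith("_total")} |
                  {c[:-3] for c in columns if c[-3:] in ("_F1", "_F2", "_F3", "_F4")})


def _cell(path, row, col) -> str:
    return f"{path}: row {row!r}, column {col!r}"


def read_sites(path) -> list[SiteRecord]:
    """Read a wide-format site table; validates units-by-convention (mg/kg).

    Errors name the offending row and column for missing mandatory
    columns, non-numeric cells, negative concentrations, and duplicate
    site ids.  Mass-balance disagreement between fraction sums and totals
    only logs a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    return _records_from_wide(df, str(path))


def _records_from_wide(df: pd.DataFrame, path: str) -> list[SiteRecord]:
    if "site_id" not in df.columns:
        raise ValueError(f"{path}: mandatory column 'site_id' is missing")
    ids = df["site_id"].astype(str)
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate site ids {dup}")
    metals = _metals_in_columns(df.columns)
    if not metals:
        raise ValueError(
            f"{path}: no '<metal>_total' or '<metal>_F1..F4' columns found"
        )

    sites = []
    for _, row in df.iterrows():
        sid = str(row["site_id"])
        totals: dict[str, float] = {}
        fractions: dict[str, FractionVector] = {}
        props: dict[str, float] = {}
        for m in metals:
            tcol = f"{m}_total"
            if tcol in df.columns and pd.notna(row[tcol]):
                v = _to_number(row[tcol], path, sid, tcol)
                if v < 0:
                    raise ValueError(
                        f"negative concentration at {_cell(path, sid, tcol)}"
                    )
                totals[m] = v
            fcols = [f"{m}_{f}" for f in FRACTION_NAMES]
            if all(c in df.columns for c in fcols) and row[fcols].notna().all():
                vals = []
                for c in fcols:
                    v = _to_number(row[c], path, sid, c)
                    if v < 0:
                        raise ValueError(
                            f"negative concentration at {_cell(path, sid, c)}"
                        )
                    vals.append(v)
                fractions[m] = FractionVector(*vals)
        for p in PROPERTY_NAMES:
            if p in df.columns and pd.notna(row[p]):
                props[p] = _to_number(row[p], path, sid, p)
        sites.append(
            SiteRecord(site_id=sid, totals=totals, fractions=fractions, properties=props)
        )
    return sites


def _to_number(v, path, row, col) -> float:
    try:
        return float(v)
    except (TypeError, ValueError):
        raise ValueError(f"non-numeric cell at {_cell(path, row, col)}: {v!r}") from None


def read_sites_long(path) -> list[SiteRecord]:
    """Read a long-format table with columns site_id, metal, variable, value.

    ``variable`` is one of ``total``, ``F1``..``F4``, or a property name
    (then ``metal`` is left blank).
    """
    path = Path(path)
    df = pd.read_csv(path)
    needed = {"site_id", "metal", "variable", "value"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    wide_rows: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        sid = str(row["site_id"])
        var = str(row["variable"])
        metal = row["metal"]
        col = var if pd.isna(metal) or metal == "" else f"{metal}_{var}"
        wide_rows.setdefault(sid, {})[col] = _to_number(row["value"], path, sid, col)
    wide = pd.DataFrame.from_dict(wide_rows, orient="index")
    wide.index.name = "site_id"
    return _records_from_wide(wide.reset_index(), str(path))


def write_sites(sites: list[SiteRecord], path) -> None:
    """Write site records in the wide CSV layout (round-trips read_sites)."""
    metals = sorted({m for s in sites for m in set(s.totals) | set(s.fractions)})
    props = sorted({p for s in sites for p in s.properties},
                   key=lambda p: PROPERTY_NAMES.index(p) if p in PROPERTY_NAMES else 99)
    rows = []
    for s in sites:
        row: dict[str, object] = {"site_id": s.site_id}
        for m in metals:
            if m in s.totals:
                row[f"{m}_total"] = s.totals[m]
            if m in s.fractions:
                for fname, v in zip(FRACTION_NAMES, s.fractions[m].as_tuple()):
                    row[f"{m}_{fname}"] = v
        for p in props:
            if p in s.properties:
                row[p] = s.properties[p]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    sites: list[SiteRecord]
    index_background: BackgroundSet = SHAANXI_BACKGROUND
    exceedance_background: BackgroundSet = CHINA_BACKGROUND
    tox: ToxicityParams = STUDY_TOXICITY
    mode: str = "both"  # classic | modified | both
    mc_enabled: bool = True
    n_draws: int = 50_000
    seed: int = 0
    alpha: float = 0.05
    out_dir: Path | None = None
    metals: list[str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("classic", "modified", "both"):
            raise ValueError(f"mode must be classic|modified|both, got {self.mode!r}")
        if self.mc_enabled and self.n_draws < 1000:
            raise ValueError("need n_draws >= 1000 when Monte Carlo is enabled")
        if not self.sites:
            raise ValueError("need at least one site")


_CONFIG_SCHEMA_VERSION = 1
_NAMED_BACKGROUNDS = {"Shaanxi": SHAANXI_BACKGROUND, "China": CHINA_BACKGROUND}


def load_run_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    Recognized keys (all optional except ``input``): ``schema_version``
    (must be 1 when present), ``input`` (site CSV path, resolved relative
    to the config file), ``mode``, ``index_background`` /
    ``exceedance_background`` (a named set, "Shaanxi" or "China", or a
    ``{provenance, values}`` mapping), ``tr`` and ``theta`` (toxicity
    overrides), ``mc: {enabled, n_draws, seed, alpha}``, ``out_dir``.
    Defaults reproduce the shipped study constants exactly.
    """
    import yaml

    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    version = raw.get("schema_version", _CONFIG_SCHEMA_VERSION)
    if version != _CONFIG_SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema_version {version!r}")
    if "input" not in raw:
        raise ValueError(f"{path}: mandatory key 'input' is missing")
    sites = read_sites((path.parent / raw["input"]).resolve())

    def background(key, default):
        val = raw.get(key)
        if val is None:
            return default
        if isinstance(val, str):
            try:
                return _NAMED_BACKGROUNDS[val]
            except KeyError:
                raise ValueError(f"{path}: unknown background set {val!r}") from None
        return BackgroundSet(provenance=val["provenance"], values=dict(val["values"]))

    tox = STUDY_TOXICITY
    if "tr" in raw or "theta" in raw:
        tox = ToxicityParams(
            tr={k: float(v) for k, v in raw.get("tr", STUDY_TOXICITY.tr).items()},
            theta=tuple(raw.get("theta", STUDY_TOXICITY.theta)),
        )
    mc = raw.get("mc", {})
    return RunConfig(
        sites=sites,
        index_background=background("index_background", SHAANXI_BACKGROUND),
        exceedance_background=background("exceedance_background", CHINA_BACKGROUND),
        tox=tox,
        mode=raw.get("mode", "both"),
        mc_enabled=bool(mc.get("enabled", True)),
        n_draws=int(mc.get("n_draws", 50_000)),
        seed=int(mc.get("seed", 0)),
        alpha=float(mc.get("alpha", 0.05)),
        out_dir=Path(raw["out_dir"]) if raw.get("out_dir") else None,
        metals=raw.get("metals"),
    )


def _descriptive_table(cfg: RunConfig, metals: list[str]) -> pd.DataFrame:
    rows = []
    for m in metals:
        tot = np.array([s.totals[m] for s in cfg.sites if m in s.totals])
        row: dict[str, object] = {"metal": m, "n": len(tot)}
        if len(tot) >= 2:
            row |= {
                "mean": tot.mean(),
                "sd": tot.std(ddof=1),
                "cv_pct": coefficient_of_variation(tot),
                "exceedance_pct": exceedance_rate(
                    tot, cfg.exceedance_background[m]
                ),
                "background_multiple": tot.mean() / cfg.exceedance_background[m],
            }
        profs = [
            fraction_profile(s.fractions[m], m).percentages
            for s in cfg.sites
            if m in s.fractions and s.fractions[m].fraction_sum > 0
        ]
        if profs:
            for f in FRACTION_NAMES:
                row[f"{f}_share_pct"] = float(np.mean([p[f] for p in profs]))
        rows.append(row)
    return pd.DataFrame(rows)


def _index_tables(cfg: RunConfig, metals, mode) -> tuple[pd.DataFrame, pd.DataFrame]:
    er_scheme = derive_er_scheme(cfg.tox)
    ri_scheme = derive_ri_scheme(cfg.tox)
    rows = []
    for s in cfg.sites:
        res = assess_site(
            s, cfg.index_background, cfg.tox, mode=mode,
            er_scheme=er_scheme, ri_scheme=ri_scheme, metals=metals,
        )
        nan = float("nan")
        for m, mr in res.metals.items():
            rows.append(
                {
                    "site_id": s.site_id, "mode": mode, "metal": m,
                    "igeo": nan if mr.igeo is None else mr.igeo,
                    "pollution_degree": mr.pollution_degree or "",
                    "cr_corrected": nan if mr.cr_corrected is None else mr.cr_corrected,
                    "cr_secondary": nan if mr.cr_secondary is None else mr.cr_secondary,
                    "cf": mr.cf, "er": mr.er, "risk_class": mr.risk_class,
                    "ri": res.ri, "ri_class": res.ri_class,
                }
            )
    table = pd.DataFrame(rows)
    # class-percentage summary: share of sites per risk class and metal
    pct_rows = []
    for m in metals:
        sub = table[table["metal"] == m]
        counts = sub["risk_class"].value_counts()
        for label in er_scheme.labels:
            pct_rows.append(
                {"mode": mode, "index": f"Er[{m}]", "class": label,
                 "percent_of_sites": 100.0 * counts.get(label, 0) / len(sub)}
            )
    ri_by_site = table.drop_duplicates("site_id")
    counts = ri_by_site["ri_class"].value_counts()
    for label in ri_scheme.labels:
        pct_rows.append(
            {"mode": mode, "index": "RI", "class": label,
             "percent_of_sites": 100.0 * counts.get(label, 0) / len(ri_by_site)}
        )
    return table, pd.DataFrame(pct_rows)


def _mc_tables(cfg: RunConfig, metals) -> dict[str, pd.DataFrame]:
    # random variables are the fraction-corrected concentrations per metal
    specs = {}
    for m in metals:
        labels = [s.site_id for s in cfg.sites if m in s.fractions]
        cri = [
            corrected_concentration(s.fractions[m], cfg.tox.theta)
            for s in cfg.sites
            if m in s.fractions
        ]
        specs[m] = fit_distribution(cri, alpha=cfg.alpha, metal=m, labels=labels)
    result = propagate(
        specs,
        cfg.index_background,
        cfg.tox,
        n=cfg.n_draws,
        seed=cfg.seed,
    )
    spec_rows = [
        {
            "metal": m, "family": sp.family, "loc": sp.loc, "scale": sp.scale,
            "sw_p_raw": sp.sw_p_raw, "sw_p_log": sp.sw_p_log,
            "outliers_removed": ";".join(sp.outliers_removed),
            "warning": sp.warning or "",
            "rejected_draws": result.rejected_draws.get(m, 0),
        }
        for m, sp in specs.items()
    ]
    prob_rows = [
        {"index": k, "class": label, "probability_pct": 100.0 * p}
        for k, table in result.class_probs.items()
        for label, p in table.items()
    ]
    pct_rows = [
        {"index": k, **{q: v for q, v in qs.items()}}
        for k, qs in result.percentiles.items()
    ]
    sens_rows = [
        {"metal": m, "contribution_pct": v} for m, v in result.sensitivity.items()
    ]
    return {
        "mc_specs": pd.DataFrame(spec_rows),
        "mc_class_probabilities": pd.DataFrame(prob_rows),
        "mc_percentiles": pd.DataFrame(pct_rows),
        "mc_sensitivity": pd.DataFrame(sens_rows).sort_values(
            "contribution_pct", ascending=False, ignore_index=True
        ),
    }


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute descriptive → indices → Monte Carlo and collect every table.

    Returns a dict of DataFrames; when ``cfg.out_dir`` is set, each table
    is also written as ``<name>.csv`` together with ``run_log.json``
    holding the resolved parameter provenance (background sets, θ, Tr,
    seed, draw count).
    """
    metals = cfg.metals or sorted(cfg.tox.tr)
    tables: dict[str, pd.DataFrame] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    tables["descriptive"] = stage("descriptive", lambda: _descriptive_table(cfg, metals))

    modes = ["classic", "modified"] if cfg.mode == "both" else [cfg.mode]
    site_frames, pct_frames = [], []
    for mode in modes:
        t, p = stage(f"indices[{mode}]", lambda mode=mode: _index_tables(cfg, metals, mode))
        site_frames.append(t)
        pct_frames.append(p)
    tables["site_indices"] = pd.concat(site_frames, ignore_index=True)
    tables["class_percentages"] = pd.concat(pct_frames, ignore_index=True)

    if cfg.mc_enabled:
        tables |= stage("monte_carlo", lambda: _mc_tables(cfg, metals))

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        log = {
            "index_background": {
                "provenance": cfg.index_background.provenance,
                "values": cfg.index_background.values,
            },
            "exceedance_background": {
                "provenance": cfg.exceedance_background.provenance,
                "values": cfg.exceedance_background.values,
            },
            "toxicity": {"tr": cfg.tox.tr, "theta": list(cfg.tox.theta)},
            "mode": cfg.mode,
            "mc": {"enabled": cfg.mc_enabled, "n_draws": cfg.n_draws,
                   "seed": cfg.seed, "alpha": cfg.alpha},
            "n_sites": len(cfg.sites),
            "metals": metals,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return tables
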