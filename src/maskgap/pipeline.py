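"""End-to-end run: simulate -> preprocess -> allocate -> demand -> fit -> evaluate.

Stages communicate through files (GeoJSON / CSV) inside a run directory so
each stage can be inspected or re-run on its own. A manifest JSON records
the seed, configuration, per-stage wall time and row counts, and any
warnings (non-convergence, MAPE exclusions), so a run is reproducible from
the manifest alone. Choropleth maps of the raw and modeled relative risks
and of the undersupply probability Pr(RR < 1) are exported per fitted
model, with the color scale anchored at RR = 1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bhm, demand, evaluation, inventory, spatial_alloc, synthgen
from ._geojson import frame_to_geojson


@dataclass
class RunConfig:
    out_dir: str = "maskgap_run"
    seed: int = 0
    n_villages: int = 200
    n_stores: int = 120
    region_size: float = 20_000.0
    n_days: int = 7
    quota: int = 9
    restock_prob_per_day: float = 0.7
    models: tuple = ("poisson", "negbin", "poisson_spatial", "negbin_spatial")
    chains: int = 2
    iterations: int = 2000
    burnin: int = 1000
    thin: int = 2
    exceedance_threshold: float = 1.0
    family_truth: str = "poisson"
    make_maps: bool = True

    def __post_init__(self):
        if self.exceedance_threshold <= 0:
            raise ValueError("exceedance threshold must be > 0")


def _spec_for(name: str, cfg: RunConfig, seed: int) -> bhm.ModelSpec:
    family = "negbin" if name.startswith("negbin") else "poisson"
    return bhm.ModelSpec(
        family=family,
        spatial=name.endswith("_spatial"),
        chains=cfg.chains,
        iterations=cfg.iterations,
        burnin=cfg.burnin,
        thin=cfg.thin,
        seed=seed,
    )


def run(cfg: RunConfig) -> Path:
    """Execute the full pipeline on a synthetic region; returns the run dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "stages": {},
        "warnings": [],
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 3)
                }
                return False

        return _Ctx()

    scfg = synthgen.SyntheticConfig(
        n_villages=cfg.n_villages,
        n_stores=cfg.n_stores,
        region_size=cfg.region_size,
        seed=cfg.seed,
        quota=cfg.quota,
        n_days=cfg.n_days,
        restock_prob_per_day=cfg.restock_prob_per_day,
        family=cfg.family_truth,
    )
    region = synthgen.region_polygon(scfg)

    with stage("simulate"):
        villages = synthgen.generate_villages(scfg)
        stores = synthgen.generate_stores(scfg)
        inv, ledger, events = synthgen.generate_inventory(scfg, stores)
        inv.to_csv(out / "inventory.csv", index=False)
        stores[["store_id", "x", "y"]].to_csv(out / "stores.csv", index=False)
        ledger.to_csv(out / "sales_ledger.csv", index=False)
        events.to_csv(out / "restock_events.csv", index=False)
    manifest["stages"]["simulate"]["rows"] = {
        "villages": len(villages),
        "stores": len(stores),
        "inventory": len(inv),
    }

    with stage("preprocess"):
        supply = inventory.preprocess_inventory(inv, stores, quota=cfg.quota)
        supply.to_csv(out / "supply.csv", index=False)

    with stage("allocate"):
        surface = spatial_alloc.build_voronoi(supply, region)
        villages = spatial_alloc.areal_interpolate(surface, villages)
        villages["store_count"] = spatial_alloc.count_stores_in_village(
            supply, villages
        ).astype(float)

    with stage("demand"):
        villages = demand.attach_expected(villages)
        villages["label_raw"] = demand.classify_raw(villages["rho_raw"])
        frame_to_geojson(villages, str(out / "villages.geojson"))

    with stage("screen"):
        evaluation.vif(villages).to_csv(out / "vif.csv", header=["vif"])

    adj = bhm.build_adjacency(villages)
    edges = np.argwhere(np.triu(adj.a) > 0)
    pd.DataFrame(edges, columns=["i", "j"]).to_csv(out / "adjacency.csv", index=False)

    fits, scores = {}, []
    seed_rng = np.random.default_rng(cfg.seed)
    for name in cfg.models:
        with stage(f"fit_{name}"):
            spec = _spec_for(name, cfg, int(seed_rng.integers(0, 2**31 - 1)))
            fit = bhm.fit(spec, villages, adj)
            fits[name] = fit
            if not fit.converged:
                manifest["warnings"].append(f"{name}: R-hat > 1.1 on a fixed effect")
            fit.summary.to_csv(out / f"posterior_{name}.csv", index=False)
            per = fit.rho_summary()
            per["pr_under"] = bhm.exceedance(fit, cfg.exceedance_threshold)
            per.insert(
                0, "village_id", villages.loc[fit.modeled, "village_id"].to_numpy()
            )
            per.to_csv(out / f"villages_{name}.csv", index=False)
            sc = evaluation.score(
                fit, villages.loc[fit.modeled, "rho_raw"].to_numpy()
            )
            scores.append(sc)
            if sc.mape_excluded:
                manifest["warnings"].append(
                    f"{name}: {sc.mape_excluded} zero-RR villages excluded from MAPE"
                )

    with stage("evaluate"):
        evaluation.comparison_table(scores).to_csv(out / "scores.csv", index=False)

    if cfg.make_maps:
        with stage("maps"):
            export_maps(villages, fits, out, threshold=cfg.exceedance_threshold)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


# ---------------------------------------------------------------------------
# choropleths


def export_maps(
    villages: pd.DataFrame,
    fits: dict | None,
    out_dir,
    threshold: float = 1.0,
) -> list:
    """Choropleths of raw RR, modeled RR per fit, and Pr(RR < threshold).

    RR maps use a diverging scale anchored at RR = 1 (white), so under- and
    over-supplied villages read as opposite colors. Missing fits degrade
    gracefully to a raw-RR map only. Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [
        _choropleth(
            villages,
            villages["rho_raw"].to_numpy(dtype=float),
            out / "map_rr_raw.png",
            "raw relative risk of supply",
            diverging_at=1.0,
        )
    ]
    for name, fit in (fits or {}).items():
        rho = np.full(len(villages), np.nan)
        rho[fit.modeled] = fit.rho_draws().mean(axis=0)
        paths.append(
            _choropleth(
                villages,
                rho,
                out / f"map_rr_{name}.png",
                f"posterior mean RR ({name})",
                diverging_at=1.0,
            )
        )
        pr = np.full(len(villages), np.nan)
        pr[fit.modeled] = bhm.exceedance(fit, threshold)
        paths.append(
            _choropleth(
                villages,
                pr,
                out / f"map_pr_under_{name}.png",
                f"Pr(RR < {threshold:g}) ({name})",
                vmin=0.0,
                vmax=1.0,
            )
        )
    return paths


def _choropleth(villages, values, path, title, diverging_at=None, vmin=None, vmax=None):
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    lo = float(finite.min()) if len(finite) else 0.0
    hi = float(finite.max()) if len(finite) else 1.0
    if diverging_at is not None:
        # symmetric log-scale span around the anchor so RR=1 sits at center
        span = max(abs(np.log(max(lo, 1e-6))), abs(np.log(max(hi, 1e-6))), 0.1)
        norm_vals = np.log(np.clip(values, 1e-6, None))
        vmin, vmax, cmap = -span, span, "RdBu"
    else:
        norm_vals = values
        vmin = lo if vmin is None else vmin
        vmax = hi if vmax is None else vmax
        cmap = "viridis"

    fig, ax = plt.subplots(figsize=(7, 6))
    verts, facevals = [], []
    for geom, val in zip(villages["geometry"], norm_vals):
        polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
        for p in polys:
            verts.append(np.asarray(p.exterior.coords))
            facevals.append(val)
    coll = PolyCollection(verts, array=np.asarray(facevals), cmap=cmap, edgecolor="0.4", linewidth=0.2)
    coll.set_clim(vmin, vmax)
    ax.add_collection(coll)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_title(title)
    cb = fig.colorbar(coll, ax=ax, shrink=0.8)
    if diverging_at is not None:
        ticks = cb.get_ticks()
        cb.set_ticks(ticks)
        cb.set_ticklabels([f"{np.exp(t):.2g}" for t in ticks])
        cb.set_label("RR (log-spaced)")
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
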