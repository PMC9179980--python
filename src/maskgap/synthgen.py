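"""Synthetic study regions, stores, inventory traces and village counts.

Emulates the data-generating structure of the mask supply study design:

* a planar square study region tiled by village polygons (Voronoi cells of
  random seed points), each with an adult population and six covariates
  (pharmacy count, median income, and four land-use percentages);
* per-store 10-minute inventory traces: piecewise-constant stock levels with
  sales decrements spread over business hours and occasional restocking
  jumps, plus a ground-truth ledger of realized sales;
* village-level supply counts drawn from the Besag-York-Mollie count model
  (Poisson or negative binomial likelihood, log-linear fixed effects on the
  covariates, ICAR spatial + iid normal random effects) at known parameter
  values, so downstream estimation can be validated by parameter recovery.

Every draw is governed by one global seed through named sub-streams, so a
fixed seed reproduces each artifact bit-identically even if only part of the
generator is re-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

# Covariates in the order they enter the log-linear predictor (after the
# intercept). Income enters the model as log(income); see bhm.design_matrix.
COVARIATES = (
    "store_count",
    "income",
    "business_pct",
    "residential_pct",
    "mixed_pct",
    "school_pct",
)

# Independent sub-stream ids for the global seed.
_STREAMS = {
    "villages": 11,
    "population": 12,
    "covariates": 13,
    "stores": 21,
    "inventory": 22,
    "effects": 31,
    "counts": 32,
}

#: Study-scale truth used as generator defaults: intercept and slopes for
#: (store count, log income, business %, residential %, mixed %, school %)
#: followed by the two random-effect precisions. These are the magnitudes a
#: metropolitan pharmacy-access analysis produces, so synthetic regions have
#: realistic relative-risk surfaces.
DEFAULT_COEFFICIENTS = (3.702, 0.124, -0.565, 0.559, -2.821, -0.990, 0.467)
DEFAULT_PRECISION_SPATIAL = 0.497
DEFAULT_PRECISION_IID = 6.380


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study region and data-generating model.

    The defaults mirror the study conditions: a ~1500-village metropolitan
    region observed for 49 days under a nine-masks-per-two-weeks rationing
    quota, with supply counts generated from the BYM log-linear model.
    """

    n_villages: int = 1488
    n_stores: int = 1774
    region_size: float = 57_000.0  # meters, square side
    seed: int = 0
    quota: int = 9  # masks per person per two weeks
    n_days: int = 49
    restock_prob_per_day: float = 0.7
    true_coefficients: tuple = DEFAULT_COEFFICIENTS
    precision_spatial: float = DEFAULT_PRECISION_SPATIAL
    precision_iid: float = DEFAULT_PRECISION_IID
    family: str = "poisson"
    size_parameter: float = 1.6  # NB size, ignored for Poisson
    pop_median: float = 4268.0
    pop_sigma: float = 0.8
    business_hours: tuple = (9, 21)  # sales occur in [start, end) o'clock
    mean_store_sales: float = 900.0  # masks/day, lognormal median per store

    def __post_init__(self):
        if self.n_villages < 2:
            raise ValueError("n_villages must be >= 2 (no adjacency possible)")
        if self.quota < 1:
            raise ValueError("quota must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.precision_spatial <= 0 or self.precision_iid <= 0:
            raise ValueError("precisions must be > 0")
        if not 0.0 <= self.restock_prob_per_day <= 1.0:
            raise ValueError("restock_prob_per_day must be in [0, 1]")
        if self.family not in ("poisson", "negbin"):
            raise ValueError("family must be 'poisson' or 'negbin'")
        if len(self.true_coefficients) != 7:
            raise ValueError("true_coefficients must have 7 entries (b0..b6)")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, seed-derived random stream."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) % 2**31, _STREAMS[stream]])
        )

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated count vector."""

    coefficients: np.ndarray  # b0..b6
    u: np.ndarray  # ICAR spatial effects
    v: np.ndarray  # iid effects
    rho: np.ndarray  # true relative risks exp(eta)
    lam: np.ndarray  # true means E_i * rho_i


def region_polygon(cfg: SyntheticConfig) -> Polygon:
    s = float(cfg.region_size)
    return box(0.0, 0.0, s, s)


# ---------------------------------------------------------------------------
# villages


def generate_villages(cfg: SyntheticConfig) -> pd.DataFrame:
    """Tile the square region into village polygons with population and covariates.

    Villages are Voronoi cells of uniform random points, clipped to the
    region, so they tile the square exactly and form a connected contiguity
    graph. Adult population is lognormal around ``pop_median``; covariates
    have the marginal shapes seen in metropolitan villages: a small-count
    pharmacy number, lognormal median income (thousand currency units), and
    four land-use shares from a Dirichlet draw so their sum stays below 1.
    """
    region = region_polygon(cfg)
    rng = cfg.rng("villages")
    pts = rng.uniform(0.0, cfg.region_size, size=(cfg.n_villages, 2))
    cells = _voronoi_cells(pts, region)

    prng = cfg.rng("population")
    pop = prng.lognormal(np.log(cfg.pop_median), cfg.pop_sigma, cfg.n_villages)
    pop = np.maximum(np.round(pop), 1.0)

    crng = cfg.rng("covariates")
    store = np.minimum(crng.poisson(1.1, cfg.n_villages), 9)
    income = crng.lognormal(np.log(439.0), 0.25, cfg.n_villages)
    # shares: business, residential, mixed, school, other (unused)
    shares = crng.dirichlet([0.4, 1.3, 1.1, 0.25, 3.0], cfg.n_villages)

    frame = pd.DataFrame(
        {
            "village_id": [f"V{i:04d}" for i in range(cfg.n_villages)],
            "geometry": cells,
            "pop": pop,
            "store_count": store.astype(float),
            "income": income,
            "business_pct": shares[:, 0],
            "residential_pct": shares[:, 1],
            "mixed_pct": shares[:, 2],
            "school_pct": shares[:, 3],
        }
    )
    return frame


def _voronoi_cells(points: np.ndarray, region: Polygon) -> list:
    """Voronoi cells of `points` clipped to `region`, in point order."""
    diagram = voronoi_diagram(
        MultiPoint([Point(p) for p in points]), envelope=region.buffer(region.length)
    )
    raw = list(diagram.geoms)
    tree = STRtree(raw)
    cells = []
    for p in points:
        pt = Point(p)
        idx = [i for i in tree.query(pt, predicate="intersects")]
        if not idx:  # numeric edge case: fall back to nearest cell
            idx = [tree.nearest(pt)]
        # a point on a shared Voronoi edge intersects two cells; take the
        # one whose interior is nearest to the generator
        best = min(idx, key=lambda i: raw[i].centroid.distance(pt))
        cells.append(raw[best].intersection(region))
    return cells


# ---------------------------------------------------------------------------
# stores & inventory


def generate_stores(cfg: SyntheticConfig) -> pd.DataFrame:
    """Store locations (uniform in the region) with mean daily sales volumes."""
    rng = cfg.rng("stores")
    xy = rng.uniform(0.0, cfg.region_size, size=(cfg.n_stores, 2))
    sales = rng.lognormal(np.log(cfg.mean_store_sales), 0.7, cfg.n_stores)
    return pd.DataFrame(
        {
            "store_id": [f"S{i:04d}" for i in range(cfg.n_stores)],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "daily_sales_mean": sales,
        }
    )


START_DATE = pd.Timestamp("2020-04-09")
_BINS_PER_DAY = 144  # 10-minute bins


def generate_inventory(
    cfg: SyntheticConfig,
    stores: pd.DataFrame,
    daily_sales: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate 10-minute inventory traces for each store.

    Within each day the realized sales (Poisson around the store's mean)
    are spread multinomially over the business-hour bins; restocking events
    refill the stock to its initial capacity with probability
    ``restock_prob_per_day`` per day, at a uniformly chosen bin. Stock never
    goes negative: decrements that would overdraw are truncated (lost sales)
    and the ledger records what was actually applied.

    Returns ``(inventory, ledger, events)``:

    * inventory — rows (store_id, timestamp, stock) on the full 10-min grid;
    * ledger — rows (store_id, date, true_sales) of applied decrements;
    * events — rows (store_id, timestamp, amount) of restock jumps.
    """
    rng = cfg.rng("inventory")
    if daily_sales is None:
        daily_sales = stores["daily_sales_mean"].to_numpy()
    daily_sales = np.asarray(daily_sales, dtype=float)
    if np.any(daily_sales < 0):
        raise ValueError("daily_sales must be non-negative")

    h0, h1 = cfg.business_hours
    biz_bins = np.arange(h0 * 6, h1 * 6)
    grid = START_DATE + pd.to_timedelta(
        np.arange(cfg.n_days * _BINS_PER_DAY) * 10, unit="min"
    )

    inv_rows, ledger_rows, event_rows = [], [], []
    for s, (_, st) in enumerate(stores.iterrows()):
        capacity = max(int(np.ceil(3 * daily_sales[s])), 50)
        stock = capacity
        trace = np.empty(cfg.n_days * _BINS_PER_DAY, dtype=np.int64)
        for d in range(cfg.n_days):
            planned = rng.poisson(daily_sales[s]) if daily_sales[s] > 0 else 0
            decrements = np.zeros(_BINS_PER_DAY, dtype=np.int64)
            if planned > 0:
                decrements[biz_bins] = rng.multinomial(
                    planned, np.full(len(biz_bins), 1.0 / len(biz_bins))
                )
            restock_bin = -1
            if cfg.restock_prob_per_day > 0 and rng.random() < cfg.restock_prob_per_day:
                restock_bin = int(rng.integers(0, _BINS_PER_DAY))
            applied = 0
            for b in range(_BINS_PER_DAY):
                if b == restock_bin and stock < capacity:
                    amount = capacity - stock
                    stock = capacity
                    event_rows.append(
                        (st["store_id"], grid[d * _BINS_PER_DAY + b], amount)
                    )
                sold = min(decrements[b], stock)
                stock -= sold
                applied += sold
                trace[d * _BINS_PER_DAY + b] = stock
            ledger_rows.append(
                (
                    st["store_id"],
                    (START_DATE + pd.Timedelta(days=d)).date(),
                    applied,
                    capacity,
                )
            )
        inv_rows.append(
            pd.DataFrame(
                {"store_id": st["store_id"], "timestamp": grid, "stock": trace}
            )
        )

    inventory = pd.concat(inv_rows, ignore_index=True)
    ledger = pd.DataFrame(
        ledger_rows, columns=["store_id", "date", "true_sales", "initial_stock"]
    )
    events = pd.DataFrame(event_rows, columns=["store_id", "timestamp", "amount"])
    return inventory, ledger, events


# ---------------------------------------------------------------------------
# counts from the BYM model


def draw_icar(
    adjacency: np.ndarray, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample an intrinsic CAR (ICAR) vector on its proper subspace.

    The ICAR precision is (1/sigma2)(D - A), which is singular: its null
    space is spanned by the indicator vectors of the connected components.
    We eigendecompose D - A, drop the (near-)zero eigenvalues, and sample
    independent normals along the remaining eigenvectors. The draw is
    automatically sum-to-zero on every connected component, and islands
    (components of size one) get exactly zero.
    """
    A = np.asarray(adjacency, dtype=float)
    n = A.shape[0]
    Q = np.diag(A.sum(axis=1)) - A
    eigval, eigvec = np.linalg.eigh(Q)
    keep = eigval > 1e-8 * max(eigval.max(), 1.0)
    z = rng.standard_normal(int(keep.sum()))
    u = eigvec[:, keep] @ (z / np.sqrt(eigval[keep])) * np.sqrt(sigma2)
    return u


def simulate_counts(
    frame: pd.DataFrame,
    cfg: SyntheticConfig,
    adjacency: np.ndarray | None = None,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Draw village supply counts from the BYM model at the config's truth.

    Requires expected counts ``E`` in the frame (run the demand stage
    first). Forms log rho_i = b0 + b.x_i + u_i + v_i with u ICAR
    (variance 1/precision_spatial) and v iid normal
    (variance 1/precision_iid), then draws Y_i ~ Poisson(E_i rho_i) or the
    negative binomial with mean E_i rho_i and variance lam + lam^2/size.
    """
    from .bhm import build_adjacency, design_matrix

    if "E" not in frame.columns:
        raise ValueError("frame lacks expected counts E; run demand first")
    E = frame["E"].to_numpy(dtype=float)
    if np.any(E <= 0):
        raise ValueError("all E_i must be positive to simulate counts")
    if cfg.family == "negbin" and cfg.size_parameter <= 0:
        raise ValueError("size_parameter must be > 0 for the negative binomial")

    if adjacency is None:
        adjacency = build_adjacency(frame).a

    b = np.asarray(cfg.true_coefficients, dtype=float)
    erng = cfg.rng("effects")
    u = draw_icar(adjacency, 1.0 / cfg.precision_spatial, erng)
    v = erng.normal(0.0, np.sqrt(1.0 / cfg.precision_iid), len(frame))

    X = design_matrix(frame)
    rho = np.exp(X @ b + u + v)
    lam = E * rho

    crng = cfg.rng("counts")
    if cfg.family == "poisson":
        Y = crng.poisson(lam)
    else:
        theta = cfg.size_parameter
        Y = crng.negative_binomial(theta, theta / (theta + lam))
    return Y.astype(np.int64), SyntheticTruth(b, u, v, rho, lam)
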