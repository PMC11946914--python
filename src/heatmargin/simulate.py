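"""Synthetic input generation for the full vulnerability pipeline.

Everything the downstream stages consume — tree, trait table, occurrence
table, daily operative-temperature series — is generated here with the
statistical structure the analysis assumes: lambda-structured species
intercepts, narrowly varying acclimatization slopes, heavy missingness in
the tolerance column, and microhabitat-ordered daily-maximum variance
(aquatic < arboreal < terrestrial).  One master seed reproduces every
table exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import Phylogeny

__all__ = [
    "GridSpec", "SimConfig", "SyntheticTruth",
    "simulate_tree", "simulate_traits", "simulate_trait_table",
    "simulate_ranges", "simulate_operative_temps",
    "ENDPOINTS", "MEDIA", "LIFE_STAGES", "ECOTYPES",
    "MICROHABITATS", "SCENARIO_OFFSETS", "REFERENCE_T_ACC",
]

ENDPOINTS = ["onset_of_spasms", "loss_of_righting", "other"]
MEDIA = ["water", "air"]
LIFE_STAGES = ["adult", "larva"]
ECOTYPES = ["ground-dwelling", "fossorial", "aquatic", "semi-aquatic",
            "stream-dwelling", "arboreal"]
MICROHABITATS = ["terrestrial", "arboreal", "aquatic"]
SCENARIO_OFFSETS = {"current": 0.0, "plus2": 2.0, "plus4": 4.0}

# acclimatization temperature at which species "intercepts" are defined
REFERENCE_T_ACC = 20.0


@dataclass
class GridSpec:
    """1-degree lat/lon grid; cells identified by their floor coordinates."""

    lat_min: int = -20
    lat_max: int = 20     # exclusive upper cell edge
    lon_min: int = 0
    lon_max: int = 10

    def cells(self) -> pd.DataFrame:
        lats = np.arange(self.lat_min, self.lat_max)
        lons = np.arange(self.lon_min, self.lon_max)
        la, lo = np.meshgrid(lats, lons, indexing="ij")
        la, lo = la.ravel(), lo.ravel()
        return pd.DataFrame({
            "cell_id": [cell_id(a, b) for a, b in zip(la, lo)],
            "lat": la + 0.5, "lon": lo + 0.5,
        })

    @property
    def n_cells(self) -> int:
        return (self.lat_max - self.lat_min) * (self.lon_max - self.lon_min)


def cell_id(lat_floor: int, lon_floor: int) -> str:
    return f"{int(lat_floor)}_{int(lon_floor)}"


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the analysis' working values."""

    n_species: int = 500
    prop_missing: float = 0.899
    lambda_true: float = 0.95
    arr_mean: float = 0.134
    arr_sd: float = 0.008
    ctmax_mean: float = 36.2
    phylo_sd: float = 2.5          # sd of total species-level intercepts
    residual_sd: float = 0.4       # extra within-species scatter beyond the SE
    se_log_mean: float = -0.9      # lognormal sampling-SE distribution
    se_log_sd: float = 0.5
    max_records: int = 10
    covariate_missing: float = 0.15
    missing_pattern: str = "clustered"   # clustered | random
    grid: GridSpec = field(default_factory=GridSpec)
    max_band_cells: int = 6
    years: tuple[int, ...] = tuple(range(2005, 2016))
    warming_offsets: tuple[float, ...] = (0.0, 2.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prop_missing < 1.0):
            raise ValueError("prop_missing must be in [0, 1)")
        if not (0.0 <= self.lambda_true <= 1.0):
            raise ValueError("lambda_true must be in [0, 1]")
        if not (0.0 <= self.arr_mean <= 1.0):
            raise ValueError("arr_mean outside plausible [0, 1] range")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = dataclasses.asdict(self.grid)
        d["years"] = list(self.years)
        d["warming_offsets"] = list(self.warming_offsets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = GridSpec(**d["grid"])
        if "years" in d:
            d["years"] = tuple(d["years"])
        if "warming_offsets" in d:
            d["warming_offsets"] = tuple(d["warming_offsets"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside generated tables for recovery tests."""

    species: list[str]
    intercept: np.ndarray          # true CT_max at REFERENCE_T_ACC, degC
    slope: np.ndarray              # true acclimatization response ratio
    lambda_true: float
    ecotype: list[str]
    effects: dict                  # methodological fixed effects used

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species,
            "true_intercept": self.intercept,
            "true_slope": self.slope,
            "ecotype": self.ecotype,
        })


# ---------------------------------------------------------------------
# tree

def simulate_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` labelled tips.

    Lineages split at rate ``birth_rate`` per lineage; the simulation stops
    at the n-th speciation event, so the expected root-to-tip depth is
    sum_{k=2}^{n-1} 1/(birth_rate*k).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    width = len(str(n_tips))

    class _Node:
        __slots__ = ("length", "children")

        def __init__(self) -> None:
            self.length = 0.0
            self.children: list[_Node] = []

    left, right = _Node(), _Node()
    active = [left, right]
    while len(active) < n_tips:
        k = len(active)
        t = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            node.length += t
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        parent.children = [_Node(), _Node()]
        active.extend(parent.children)

    counter = iter(range(1, n_tips + 1))

    def render(node: "_Node") -> str:
        if node.children:
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}):{node.length:.10g}"
        return f"sp{next(counter):0{width}d}:{node.length:.10g}"

    text = f"({render(left)},{render(right)});"
    return Phylogeny.from_newick(text)


# ---------------------------------------------------------------------
# traits

def _ml_variance_share(u: np.ndarray, eigvals: np.ndarray,
                       Q: np.ndarray) -> float:
    """Profile-ML phylogenetic share h for u ~ N(0, s2*(h*C + (1-h)*I))."""
    w2 = (Q.T @ u) ** 2
    n = len(u)
    grid = np.linspace(0.001, 0.999, 999)
    best_h, best_ll = 0.5, -np.inf
    for h in grid:
        d = h * eigvals + (1.0 - h)
        s2 = float(np.mean(w2 / d))
        ll = -0.5 * (np.sum(np.log(d)) + n * np.log(s2))
        if ll > best_ll:
            best_h, best_ll = h, ll
    return best_h


def _pin_variance_share(a_phylo: np.ndarray, a_species: np.ndarray,
                        ccorr: np.ndarray, target: float) -> float:
    """Bisection for the independent-component scale that makes the
    realized profile-ML share equal the target."""
    eigvals, Q = np.linalg.eigh(ccorr)
    eigvals = np.clip(eigvals, 0.0, None)

    def share(scale: float) -> float:
        return _ml_variance_share(a_phylo + scale * a_species, eigvals, Q)

    lo, hi = 0.01, 20.0
    if share(lo) < target or share(hi) > target:  # cannot bracket: keep draw
        return 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if share(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_traits(tree: Phylogeny, config: SimConfig,
                    rng: np.random.Generator | None = None,
                    exact_variance: bool = False) -> SyntheticTruth:
    """Draw true species intercepts and acclimatization slopes.

    Intercepts are the sum of a phylogenetic component with covariance
    ``lambda * phylo_sd^2 * Ccorr`` and an independent species component
    with variance ``(1-lambda) * phylo_sd^2``, so ``lambda_true`` is the
    phylogenetic share of the non-residual variance.  Slopes are
    Normal(arr_mean, arr_sd^2).

    With ``exact_variance=True`` the independent component is rescaled so
    the profile-maximum-likelihood phylogenetic share of the realized
    species intercepts equals ``lambda_true`` exactly — conditional
    simulation for calibration/coverage studies, removing the
    replicate-level fluctuation of the realized variance split.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    species = tree.tips
    n = len(species)
    ccorr = tree.covariance(lam=1.0, normalize=True).matrix
    lam = config.lambda_true
    chol = np.linalg.cholesky(ccorr + 1e-10 * np.eye(n))
    z_p = rng.standard_normal(n)
    z_s = rng.standard_normal(n)
    a_phylo = config.phylo_sd * np.sqrt(lam) * (chol @ z_p)
    a_species = config.phylo_sd * np.sqrt(1.0 - lam) * z_s
    if exact_variance and 0.0 < lam < 1.0:
        scale = _pin_variance_share(a_phylo, a_species, ccorr, lam)
        a_species = a_species * scale
    intercept = config.ctmax_mean + a_phylo + a_species
    slope = rng.normal(config.arr_mean, config.arr_sd, size=n)
    ecotype = list(rng.choice(ECOTYPES, size=n,
                              p=[0.35, 0.05, 0.1, 0.15, 0.1, 0.25]))
    effects = {
        "endpoint": {"onset_of_spasms": 0.0, "loss_of_righting": -0.8, "other": 0.5},
        "medium": {"water": 0.0, "air": 0.6},
        "life_stage": {"adult": 0.0, "larva": -1.2},
        "ecotype": {e: o for e, o in zip(
            ECOTYPES, [0.0, -0.5, -0.8, -0.3, -0.6, 0.4])},
        "ramp_rate": 1.0,        # degC per (degC/min) above reference 1.0
        "acc_duration": -0.02,   # degC per day above reference 10
        "log_body_mass": 0.15,
    }
    return SyntheticTruth(species, intercept, slope, lam, ecotype, effects)


def simulate_trait_table(truth: SyntheticTruth, config: SimConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Laboratory-style measurement table with masked data-deficient species.

    Measured species get 1..max_records rows; afterwards exactly
    ``round(prop_missing * n_species)`` species have every CT_max (and its
    SE and acclimatization temperature) masked, leaving a single
    covariate-only row.  A fraction of covariate cells is masked at random.

    With the default ``missing_pattern="clustered"`` measurement effort is
    phylogenetically clumped — measured species form contiguous runs in
    tip order, mirroring the taxonomic bias of real laboratory coverage —
    so measured species tend to have measured close relatives.
    ``"random"`` masks species uniformly instead.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(truth.species)
    n_missing = int(round(config.prop_missing * n))
    n_measured = n - n_missing
    if config.missing_pattern == "random" or n_measured == 0:
        missing_idx = set(rng.choice(n, size=n_missing, replace=False).tolist())
    elif config.missing_pattern == "clustered":
        # contiguous runs of measured tips around a few clade centers
        n_clusters = max(1, n_measured // 5)
        centers = rng.choice(n, size=n_clusters, replace=False)
        measured: set[int] = set()
        per_cluster = int(np.ceil(n_measured / n_clusters))
        for c in centers:
            lo = max(0, int(c) - per_cluster // 2)
            for i in range(lo, min(n, lo + per_cluster)):
                measured.add(i)
        pool = [i for i in range(n) if i not in measured]
        extra = n_measured - len(measured)
        if extra > 0:
            measured.update(rng.choice(pool, size=extra, replace=False).tolist())
        elif extra < 0:
            drop = rng.choice(sorted(measured), size=-extra, replace=False)
            measured.difference_update(drop.tolist())
        missing_idx = set(range(n)) - measured
    else:
        raise ValueError(f"unknown missing_pattern {config.missing_pattern!r}")

    eff = truth.effects
    rows = []
    for i, sp in enumerate(truth.species):
        is_missing = i in missing_idx
        n_rec = 1 if is_missing else int(rng.integers(1, config.max_records + 1))
        mass = float(np.exp(rng.normal(0.5, 1.0)))
        for _ in range(n_rec):
            t_acc = float(rng.uniform(14.0, 30.0))
            dur = float(rng.choice([3, 5, 7, 10, 10, 10, 14, 21]))
            ramp = float(rng.choice([0.1, 0.25, 0.5, 1.0, 1.0, 1.0]))
            endpoint = str(rng.choice(ENDPOINTS, p=[0.6, 0.3, 0.1]))
            medium = str(rng.choice(MEDIA, p=[0.7, 0.3]))
            stage = str(rng.choice(LIFE_STAGES, p=[0.8, 0.2]))
            se = float(np.exp(rng.normal(config.se_log_mean, config.se_log_sd)))
            mu = (truth.intercept[i]
                  + truth.slope[i] * (t_acc - REFERENCE_T_ACC)
                  + eff["endpoint"][endpoint]
                  + eff["medium"][medium]
                  + eff["life_stage"][stage]
                  + eff["ecotype"][truth.ecotype[i]]
                  + eff["ramp_rate"] * (ramp - 1.0)
                  + eff["acc_duration"] * (dur - 10.0)
                  + eff["log_body_mass"] * np.log(mass))
            noise = rng.normal(0.0, np.hypot(se, config.residual_sd))
            rows.append({
                "species": sp,
                "ctmax": np.nan if is_missing else mu + noise,
                "ctmax_se": np.nan if is_missing else se,
                "t_acc": np.nan if is_missing else t_acc,
                "acc_duration": dur,
                "ramp_rate": ramp,
                "endpoint": endpoint,
                "medium": medium,
                "life_stage": "adult" if is_missing else stage,
                "ecotype": truth.ecotype[i],
                "body_mass": mass,
            })
    df = pd.DataFrame(rows)

    # partial covariate masking (never the species column; keep >=1 observed)
    maskable = ["acc_duration", "ramp_rate", "endpoint", "medium", "body_mass"]
    for col in maskable:
        mask = rng.random(len(df)) < config.covariate_missing
        if mask.sum() >= len(df):
            mask[rng.integers(len(df))] = False
        df.loc[mask, col] = np.nan
    return df


# ---------------------------------------------------------------------
# occurrences

def simulate_ranges(species: list[str], grid: GridSpec, seed: int,
                    max_band_cells: int = 6) -> pd.DataFrame:
    """Contiguous latitudinal band of 1..max_band_cells cells per species."""
    if grid.n_cells == 0:
        raise ValueError("empty grid")
    rng = np.random.default_rng(seed)
    lats = np.arange(grid.lat_min, grid.lat_max)
    lons = np.arange(grid.lon_min, grid.lon_max)
    rows = []
    for sp in species:
        k = int(rng.integers(1, max_band_cells + 1))
        k = min(k, len(lats))
        start = int(rng.integers(0, len(lats) - k + 1))
        lon = int(rng.choice(lons))
        for lat in lats[start:start + k]:
            rows.append({"species": sp, "cell_id": cell_id(lat, lon),
                         "lat": lat + 0.5, "lon": lon + 0.5})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# operative temperatures

_HABITAT_NOISE_SD = {"terrestrial": 3.0, "arboreal": 2.1, "aquatic": 0.9}
_HABITAT_OFFSET = {"terrestrial": 0.0, "arboreal": -1.0, "aquatic": -2.0}
_HABITAT_AMP = {"terrestrial": 1.0, "arboreal": 0.85, "aquatic": 0.65}
_AQUATIC_SMOOTH = 5  # days; thermal-inertia lag of water bodies


def simulate_operative_temps(grid: GridSpec, years, microhabitat: str,
                             warming_offset: float, seed: int) -> pd.DataFrame:
    """Daily maximum operative body temperatures per cell and calendar day.

    Latitudinal mean gradient + hemisphere-phased seasonal sinusoid +
    autocorrelated heavy-tailed heat-wave noise + additive warming offset.
    The noise stream depends on the seed and cell only, never on the
    offset, so scenarios are exact additive shifts of one another.
    """
    if microhabitat not in MICROHABITATS:
        raise ValueError(f"unknown microhabitat {microhabitat!r}")
    years = sorted(years)
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    doy = dates.day_of_year.to_numpy()
    n_days = len(dates)
    hab_code = MICROHABITATS.index(microhabitat)

    frames = []
    cells = grid.cells()
    for _, cell in cells.iterrows():
        lat = cell["lat"]
        rng = np.random.default_rng(
            [seed, hab_code, int(np.floor(lat)) + 1000, int(np.floor(cell["lon"])) + 1000])
        base = 33.0 - 0.25 * abs(lat) + _HABITAT_OFFSET[microhabitat]
        amp = _HABITAT_AMP[microhabitat] * (2.0 + 0.15 * abs(lat))
        phase = 200.0 if lat >= 0 else 20.0  # warm season by hemisphere
        seasonal = amp * np.cos(2.0 * np.pi * (doy - phase) / 365.25)
        # AR(1) heat-wave noise with Student-t innovations
        innov = rng.standard_t(df=5, size=n_days)
        noise = np.empty(n_days)
        noise[0] = innov[0]
        for t in range(1, n_days):
            noise[t] = 0.6 * noise[t - 1] + innov[t]
        noise *= _HABITAT_NOISE_SD[microhabitat] / np.std(noise)
        series = base + seasonal + noise
        if microhabitat == "aquatic":
            series = (pd.Series(series)
                      .rolling(_AQUATIC_SMOOTH, min_periods=1).mean().to_numpy())
        series = series + warming_offset
        frames.append(pd.DataFrame({
            "cell_id": cell["cell_id"], "lat": lat, "lon": cell["lon"],
            "date": dates.strftime("%Y-%m-%d"), "year": dates.year,
            "doy": doy, "daily_max": series,
        }))
    out = pd.concat(frames, ignore_index=True)
    out["microhabitat"] = microhabitat
    scen = {v: k for k, v in SCENARIO_OFFSETS.items()}.get(warming_offset)
    out["scenario"] = scen if scen is not None else f"offset{warming_offset:g}"
    return out
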