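"""Synthetic study generator: every input the pipeline consumes, with known truth.

The generator emulates a grassland soil survey: ~150 plots measured for a
few dozen environmental variables spanning realistic ranges (pH 4.6-7.5,
organic carbon 12-360 g/kg, ...), amplicon read counts per plot whose
expectations follow HOF-shaped response curves with known optima, ultrametric
phylogenies with Brownian-motion / Ornstein-Uhlenbeck / white-noise tip
traits, reference 16S-like sequences with mutated reads, and coded trait
matrices with planted group structure and missingness.

Every generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .hof import HOFFit

__all__ = [
    "DEFAULT_VARIABLES",
    "SimulationConfig",
    "GroundTruth",
    "generate_env",
    "generate_responses",
    "sample_reads",
    "generate_tree",
    "evolve_trait",
    "plant_trait_matrices",
    "generate_reference_set",
    "mutate_reads",
    "planted_optima",
]

# Default gradient ranges of the 41 grassland environmental variables
# (soil physicochemistry, microbial biomass, plant and soil-fauna descriptors).
DEFAULT_VARIABLES: tuple[tuple[str, float, float], ...] = (
    ("BM_grassland", 3.0, 436.0),
    ("LUI", 0.6, 3.4),
    ("pH", 4.6, 7.5),
    ("C_i", 0.0, 78.5),
    ("C_o", 12.2, 359.5),
    ("C_N", 9.0, 14.6),
    ("BM_roots_F", 0.1, 53.4),
    ("BM_roots_C", 0.0, 6.8),
    ("PL_N", 1.2, 3.6),
    ("PL_C", 42.7, 46.1),
    ("PL_P", 0.1, 0.4),
    ("PL_K", 0.6, 3.8),
    ("PL_Ca", 0.2, 1.4),
    ("PL_Mg", 0.1, 0.5),
    ("Sand", 0.8, 84.6),
    ("Silt", 7.2, 86.8),
    ("Clay", 4.1, 70.8),
    ("NH4", 2.3, 51.7),
    ("NO3", 0.0, 68.8),
    ("N_min", 4.4, 112.3),
    ("Roots_C_N", 17.8, 98.1),
    ("Roots_C", 28.8, 48.5),
    ("Roots_N", 0.5, 2.4),
    ("Paur", 0.0, 16270.0),
    ("Lumb", 0.0, 1019.0),
    ("Dipl", 0.0, 207.0),
    ("Soil_H2O", 3.2, 208.5),
    ("C_mic", 116.0, 1521.0),
    ("P_mic", 3.5, 81.9),
    ("C_mic_N_mic", 4.8, 10.4),
    ("Shannon", 0.9, 3.2),
    ("Evenness", 0.4, 0.9),
    ("COV_legumes", 0.0, 60.5),
    ("COV_vasc_pl", 36.5, 244.7),
    ("NR_vasc_pl", 12.0, 64.0),
    ("COV_bryoph", 0.0, 90.0),
    ("COV_litter", 0.0, 97.0),
    ("COV_bare_soil", 0.0, 40.0),
    ("N_mic", 15.0, 222.0),
    ("Symp", 0.0, 4150.0),
    ("COV_herbs", 0.0, 100.0),
)


@dataclass
class SimulationConfig:
    """Configuration of one synthetic survey."""

    n_sites: int = 150
    variable_specs: Sequence[tuple] = DEFAULT_VARIABLES
    n_otus: int = 200
    read_depth: int = 10_000
    overdispersion: Optional[float] = None   # Dirichlet concentration; None = multinomial
    background_mass: float = 2.0             # aggregated rest-of-community expectation
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        for spec in self.variable_specs:
            name, lo, hi = spec[0], float(spec[1]), float(spec[2])
            if not lo < hi:
                raise ValueError(f"variable {name!r}: min must be < max")


@dataclass
class GroundTruth:
    """Known truth behind a simulated abundance table."""

    model_types: list[str]                 # per-OTU HOF shape
    optima: np.ndarray                     # per-OTU true optimum, [1,100] scale (NaN = none)
    widths: np.ndarray                     # slope parameter b controlling niche breadth
    curves: list[HOFFit]                   # the true response curves
    group_labels: Optional[np.ndarray] = None
    tree: Optional[dendropy.Tree] = None
    trait_process: Optional[str] = None


def generate_env(config: SimulationConfig) -> pd.DataFrame:
    """Draw a site x variable table; each variable uniform over its [min, max].

    Uniform sampling maximizes gradient coverage, which is what the response
    fitting stage needs; real surveys are unevenly covered (a documented
    difference of the generator).
    """
    rng = np.random.default_rng(config.rng_seed)
    data = {}
    for spec in config.variable_specs:
        name, lo, hi = spec[0], float(spec[1]), float(spec[2])
        data[name] = rng.uniform(lo, hi, size=config.n_sites)
    idx = pd.Index([f"site{i + 1:03d}" for i in range(config.n_sites)], name="site")
    return pd.DataFrame(data, index=idx)


def _true_curve(model: str, optimum01: float, b: float, peak: float) -> HOFFit:
    """Build a true HOF curve with a prescribed optimum and peak height."""
    if model == "I":
        a = math.log(1.0 / peak - 1.0)
        params = np.array([a])
    elif model == "II":
        # monotone; optimum01 is 0 or 1 (the favored end)
        sign = -1.0 if optimum01 >= 0.0 else 1.0
        a = math.log(1.0 / peak - 1.0) - sign * b * optimum01
        params = np.array([a, sign * b])
    elif model == "IV":
        s = math.log(max(1.0 / math.sqrt(peak) - 1.0, 1e-12))
        params = np.array([s - b * optimum01, b, s + b * optimum01])
    elif model == "V":
        b1, b2 = -b, 0.6 * b
        s = math.log(max(1.0 / math.sqrt(peak) - 1.0, 1e-12))
        params = np.array([s - b1 * optimum01, b1, s - b2 * optimum01, b2])
    else:
        raise ValueError(f"unsupported true model {model!r}")
    return HOFFit(model_type=model, params=params, max_response=1.0,
                  loglik=math.nan, aicc=math.nan, n_obs=0)


def planted_optima(config: SimulationConfig, models: Optional[Sequence[str]] = None,
                   optima_range: tuple[float, float] = (10.0, 90.0),
                   slope_range: tuple[float, float] = (8.0, 16.0),
                   peak_range: tuple[float, float] = (0.02, 0.08)) -> GroundTruth:
    """Draw per-OTU true curves along a single gradient.

    Optima are uniform over ``optima_range`` (on the [1, 100] scale), slopes
    (niche breadths) and peak heights uniform over their ranges.  Flat-model
    OTUs get a constant expected proportion at the low end of ``peak_range``.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    if models is None:
        models = ["IV"] * config.n_otus
    if len(models) != config.n_otus:
        raise ValueError("one true model per OTU required")
    optima = rng.uniform(*optima_range, size=config.n_otus)
    slopes = rng.uniform(*slope_range, size=config.n_otus)
    peaks = rng.uniform(*peak_range, size=config.n_otus)
    curves, opt_out = [], np.empty(config.n_otus)
    for i, model in enumerate(models):
        o01 = (optima[i] - 50.5) / 99.0
        curve = _true_curve(model, o01, slopes[i], peaks[i])
        curves.append(curve)
        if model == "I":
            opt_out[i] = math.nan
        elif model == "II":
            opt_out[i] = 100.0 if o01 >= 0.0 else 1.0
        elif model == "IV":
            opt_out[i] = optima[i]
        else:  # V: true argmax of the skewed curve, found on a fine grid
            grid = np.linspace(-0.5, 0.5, 100_001)
            lp = curve.log_response_internal(grid)
            opt_out[i] = 50.5 + 99.0 * grid[int(np.argmax(lp))]
    return GroundTruth(model_types=list(models), optima=opt_out,
                       widths=slopes, curves=curves)


def generate_responses(env_values, truth: GroundTruth) -> np.ndarray:
    """Expected (unnormalized) response of each OTU at each site.

    Parameters
    ----------
    env_values : array-like, shape (n_sites,)
        One gradient, rescaled to [1, 100].
    truth : GroundTruth
        True curves from :func:`planted_optima`.

    Returns
    -------
    ndarray, shape (n_otus, n_sites) with entries in [0, M].
    """
    x = np.asarray(env_values, dtype=float)
    out = np.vstack([c.predict(x) for c in truth.curves])
    if np.any(out < 0):
        raise ValueError("negative expected response")
    return out


def sample_reads(expected: np.ndarray, depth: int, seed: int,
                 overdispersion: Optional[float] = None,
                 background_mass: float = 0.0,
                 site_names=None, otu_names=None) -> pd.DataFrame:
    """Sample per-site read counts around expected responses.

    Expectations are normalized per site to multinomial probabilities and
    ``depth`` reads drawn per site; with ``overdispersion`` set, probabilities
    are first jittered by a Dirichlet draw with concentration
    ``overdispersion * p`` (smaller = noisier).

    ``background_mass`` > 0 adds one aggregated "background" row with that
    constant expectation, standing in for the rest of the community.  A survey
    models a few hundred focal OTUs out of thousands, so per-site read totals
    are far more stable than the focal curves alone would suggest; the
    background row reproduces that stability, and the planted curve shape then
    equals the expected relative-abundance shape up to a near-constant factor.

    Returns an OTU x site count table whose columns each sum to ``depth``
    (background row included when requested).
    """
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("negative expectations")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if background_mass < 0:
        raise ValueError("background_mass must be non-negative")
    if background_mass > 0:
        expected = np.vstack([
            expected,
            np.full((1, expected.shape[1]), background_mass),
        ])
    n_otus, n_sites = expected.shape
    rng = np.random.default_rng(seed)
    counts = np.empty((n_otus, n_sites), dtype=np.int64)
    for s in range(n_sites):
        col = expected[:, s]
        tot = col.sum()
        if tot <= 0:
            raise ValueError(f"site {s}: expectations not normalizable")
        p = col / tot
        if overdispersion is not None:
            alpha = np.maximum(overdispersion * p, 1e-12)
            p = rng.dirichlet(alpha)
        counts[:, s] = rng.multinomial(depth, p)
    if otu_names is None:
        otu_names = [f"OTU{i + 1:04d}" for i in range(n_otus)]
        if background_mass > 0:
            otu_names[-1] = "background"
    if site_names is None:
        site_names = [f"site{i + 1:03d}" for i in range(n_sites)]
    return pd.DataFrame(counts, index=pd.Index(otu_names, name="otu"),
                        columns=site_names)


def generate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Simulate a constant-rate pure-birth tree rescaled to unit height.

    The result is binary and exactly ultrametric: all root-to-tip path
    lengths equal 1.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    # forward-time Yule simulation from the crown split: each lineage splits
    # at total rate birth_rate * len(active); record each node's birth time.
    birth_time = {}
    active = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        birth_time[child] = 0.0
        active.append(child)
    t_now = 0.0
    while len(active) < n_tips:
        t_now += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(int(rng.integers(len(active))))
        node.edge.length = t_now - birth_time[node]
        for _ in range(2):
            child = node.new_child()
            birth_time[child] = t_now
            active.append(child)
    t_end = t_now + rng.exponential(1.0 / (birth_rate * n_tips))
    for i, leaf in enumerate(active):
        leaf.edge.length = t_end - birth_time[leaf]
        leaf.taxon = taxa[i]
    for edge in tree.preorder_edge_iter():  # rescale to unit height
        if edge.length is not None:
            edge.length /= t_end
    tree.seed_node.edge.length = None
    return tree


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def evolve_trait(tree: dendropy.Tree, process: str = "BM", sigma2: float = 1.0,
                 alpha: float = 1.0, theta: float = 0.0, root_value: float = 0.0,
                 seed: int = 0) -> pd.Series:
    """Simulate one continuous trait on the tips of an ultrametric tree.

    Processes
    ---------
    - ``"BM"``: Brownian motion with rate ``sigma2`` (variance grows linearly
      with depth).
    - ``"OU"``: Ornstein-Uhlenbeck with pull ``alpha`` toward ``theta`` and
      stationary-increment variance ``sigma2/(2 alpha)``.
    - ``"white"``: i.i.d. Normal(root_value, sigma2) tips, independent of the
      tree.
    """
    rng = np.random.default_rng(seed)
    leaves = list(tree.leaf_node_iter())
    if process == "white":
        vals = root_value + math.sqrt(sigma2) * rng.standard_normal(len(leaves))
        return pd.Series(vals, index=[lf.taxon.label for lf in leaves])
    if process not in ("BM", "OU"):
        raise ValueError(f"unknown trait process {process!r}")
    values = {tree.seed_node: root_value}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        parent = values[node.parent_node]
        if process == "BM":
            values[node] = parent + math.sqrt(sigma2 * t) * rng.standard_normal()
        else:  # OU (exact transition distribution)
            decay = math.exp(-alpha * t)
            mean = theta + (parent - theta) * decay
            var = sigma2 / (2.0 * alpha) * (1.0 - decay**2)
            values[node] = mean + math.sqrt(var) * rng.standard_normal()
    return pd.Series({lf.taxon.label: values[lf] for lf in leaves})


def plant_trait_matrices(n_species: int = 30, n_traits: int = 12,
                         n_groups: int = 3, missing_fraction: float = 0.1,
                         flip_prob: float = 0.1, seed: int = 0):
    """Two coupled species x trait matrices coded 1/2/3 with planted groups.

    Each group has a characteristic trait profile (codes in {1, 2, 3}); both
    matrices derive from the same group structure (their concordance is the
    planted signal) but use independent profiles and noise.  Entries are
    flipped to a random other code with ``flip_prob`` and masked (NaN) with
    ``missing_fraction``.

    Returns ``(matrix_a, matrix_b, labels)``.
    """
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    if n_groups > n_species:
        raise ValueError("more groups than species")
    rng = np.random.default_rng(seed)
    labels = np.sort(rng.integers(0, n_groups, size=n_species))
    # guarantee every group non-empty
    labels[:n_groups] = np.arange(n_groups)
    labels = np.sort(labels)
    species = [f"sp{i + 1:03d}" for i in range(n_species)]
    mats = []
    for rep in range(2):
        profiles = rng.integers(1, 4, size=(n_groups, n_traits)).astype(float)
        m = profiles[labels].copy()
        flips = rng.random(m.shape) < flip_prob
        m[flips] = rng.integers(1, 4, size=int(flips.sum()))
        mask = rng.random(m.shape) < missing_fraction
        m[mask] = np.nan
        mats.append(pd.DataFrame(
            m, index=pd.Index(species, name="species"),
            columns=[f"trait{j + 1:02d}" for j in range(n_traits)]))
    return mats[0], mats[1], pd.Series(labels, index=species, name="group")


_BASES = np.array(list("ACGT"))


def generate_reference_set(n_otus: int, length: int = 1400, seed: int = 0,
                           min_divergence: float = 0.05) -> dict[str, str]:
    """Synthetic full-length reference sequences, mutually >= ``min_divergence``
    divergent (each derived from a common ancestor with independent heavy
    mutation), keyed by OTU id."""
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=length)
    refs = {}
    for i in range(n_otus):
        seq = ancestor.copy()
        n_mut = max(1, int(round(2.0 * min_divergence * length)))
        pos = rng.choice(length, size=n_mut, replace=False)
        seq[pos] = (seq[pos] + rng.integers(1, 4, size=n_mut)) % 4
        refs[f"OTU{i + 1:04d}"] = "".join(_BASES[seq])
    return refs


def mutate_reads(refs: dict[str, str], reads_per_ref: int, read_length: int = 100,
                 error_rate: float = 0.005, seed: int = 0):
    """Extract reads from random positions of each reference with substitution
    errors; returns ``(read_id, site, sequence, source_otu)`` tuples."""
    rng = np.random.default_rng(seed)
    out = []
    idx = 0
    for otu, seq in refs.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        for _ in range(reads_per_ref):
            start = int(rng.integers(0, len(seq) - read_length + 1))
            frag = np.array(list(seq[start:start + read_length]))
            errs = rng.random(read_length) < error_rate
            n_err = int(errs.sum())
            if n_err:
                repl = _BASES[rng.integers(0, 4, size=n_err)]
                frag[errs] = repl
            out.append((f"read{idx:06d}", "site001", "".join(frag), otu))
            idx += 1
    return out
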