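"""Synthetic electronic-nose datasets with controllable mixing behaviour.

The generator emulates a steady-state sensor array reading methanol /
ethanol / acetone mixtures: each sensor's pure-component response is
proportional to concentration (slope matrix ``panel``), a mixture's response
defaults to the sum of pure responses, and additive Gaussian noise models
measurement scatter.  Three one-parameter departures from additivity are
available — masking (the strongest component suppresses the others'
contributions), hypoadditivity (combined signal below the sum) and synergy
(above the sum) — since real odor mixing is not always additive.

A "bench-like" preset mirrors the reference measurement campaign: a
(M, E, A) universe, 8 averaged sensor features, a near-collinear
methanol/ethanol response pair (the two alcohols smell alike to carbon-black
sensors), 133 samples split 67 train / 66 test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .data import ComponentSet, ComponentUniverse, Dataset, OdorSample

__all__ = [
    "Collinearity",
    "GeneratorConfig",
    "sample_panel",
    "make_design",
    "generate_samples",
    "bench_config",
    "generate_bench_datasets",
    "MIXTURE_LEVELS",
    "PURE_LEVELS",
]

#: concentration grid (ppm) used for mixture design points
MIXTURE_LEVELS: tuple[float, ...] = (34.0, 51.0, 68.0)
#: per-component pure concentration grids (ppm); methanol's mid level differs
PURE_LEVELS: dict[str, tuple[float, ...]] = {
    "M": (28.0, 45.0, 57.0, 68.0, 85.0),
    "E": (28.0, 45.0, 56.0, 68.0, 85.0),
    "A": (28.0, 45.0, 56.0, 68.0, 85.0),
}

MIXING_MODES = ("additive", "masking", "hypoadditive", "synergistic")


@dataclass(frozen=True)
class Collinearity:
    """Force component ``target``'s response column toward ``source``'s.

    The target column becomes ``coeff * source + (1 - coeff) * target`` plus
    multiplicative jitter of relative size ``jitter``; coeff 1.0 with jitter
    0 duplicates the column exactly.
    """

    source: str
    target: str
    coeff: float = 0.95
    jitter: float = 0.02


@dataclass(frozen=True)
class GeneratorConfig:
    universe: ComponentUniverse
    m: int = 8
    #: (low, high) of a log-uniform slope law, or an explicit (m, n) matrix
    alpha_spec: tuple[float, float] | np.ndarray = (0.1, 1.0)
    collinearity: Collinearity | None = None
    #: scalar or per-sensor additive Gaussian SD, in response units
    noise_sd: float | np.ndarray = 0.5
    mixing_mode: str = "additive"
    mode_strength: float = 0.3
    concentration_levels: tuple[float, ...] = MIXTURE_LEVELS
    seed: int = 0

    def __post_init__(self):
        if self.m < self.universe.n:
            raise ValueError("need at least as many sensors as components")
        if self.mixing_mode not in MIXING_MODES:
            raise ValueError(f"unknown mixing mode {self.mixing_mode!r}")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be non-negative")
        if any(v <= 0 for v in self.concentration_levels):
            raise ValueError("concentration levels must be positive")


def sample_panel(config: GeneratorConfig) -> np.ndarray:
    """Draw the (m, n) slope matrix; deterministic for a given seed."""
    n = config.universe.n
    if isinstance(config.alpha_spec, np.ndarray):
        panel = np.array(config.alpha_spec, dtype=float)
        if panel.shape != (config.m, n):
            raise ValueError(f"explicit panel must be {(config.m, n)}, got {panel.shape}")
    else:
        lo, hi = config.alpha_spec
        rng = np.random.default_rng(config.seed)
        panel = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(config.m, n)))
    if config.collinearity is not None:
        col = config.collinearity
        js = config.universe.index(col.source)
        jt = config.universe.index(col.target)
        rng = np.random.default_rng(config.seed + 1)
        blended = col.coeff * panel[:, js] + (1 - col.coeff) * panel[:, jt]
        panel[:, jt] = blended * (1 + col.jitter * rng.standard_normal(config.m))
    return panel


def make_design(
    universe: ComponentUniverse,
    concentration_levels,
    subsets: list[ComponentSet],
) -> list[np.ndarray]:
    """Concentration vectors covering each subset at all level combinations.

    ``concentration_levels`` is either one sequence of ppm levels shared by
    every component or a mapping from component name to its level sequence.
    The cross-product of levels runs over a subset's members (zeros
    elsewhere); duplicates are removed preserving first-seen order.
    """
    if not subsets:
        raise ValueError("need at least one component set")
    if isinstance(concentration_levels, dict):
        levels_for = lambda name: tuple(concentration_levels[name])
    else:
        shared = tuple(concentration_levels)
        levels_for = lambda name: shared
    seen: set[tuple[float, ...]] = set()
    design: list[np.ndarray] = []
    for sub in subsets:
        member_levels = [levels_for(name) for name in sub.members]
        if any(len(lv) == 0 for lv in member_levels):
            raise ValueError("empty concentration level list")
        for combo in itertools.product(*member_levels):
            c = np.zeros(universe.n)
            for name, v in zip(sub.members, combo):
                c[universe.index(name)] = float(v)
            key = tuple(c)
            if key not in seen:
                seen.add(key)
                design.append(c)
    return design


def _mixture_signal(panel: np.ndarray, c: np.ndarray, mode: str, strength: float) -> np.ndarray:
    contribs = panel * c  # (m, n) pure-component signals
    k = int(np.count_nonzero(c))
    if mode == "additive" or k <= 1:
        return contribs.sum(axis=1)
    if mode == "masking":
        # strongest pure signal dominates; the rest are attenuated
        mags = np.linalg.norm(contribs, axis=0)
        dom = int(np.argmax(mags))
        scale = np.full(c.shape[0], 1.0 - strength)
        scale[dom] = 1.0
        return (contribs * scale).sum(axis=1)
    total = contribs.sum(axis=1)
    if mode == "hypoadditive":
        return total * (1.0 + strength) ** (-(k - 1))
    # synergistic
    return total * (1.0 + strength) ** (k - 1)


def generate_samples(
    panel: np.ndarray,
    design: list[np.ndarray],
    config: GeneratorConfig,
    id_prefix: str = "",
) -> Dataset:
    """Simulate labelled, concentration-annotated samples at the design points."""
    universe = config.universe
    if panel.shape != (config.m, universe.n):
        raise ValueError(f"panel must be {(config.m, universe.n)}, got {panel.shape}")
    rng = np.random.default_rng(config.seed + 2)
    sd = np.broadcast_to(np.asarray(config.noise_sd, dtype=float), (config.m,))
    samples = []
    counters: dict[str, int] = {}
    for c in design:
        signal = _mixture_signal(panel, c, config.mixing_mode, config.mode_strength)
        noise = rng.standard_normal(config.m) * sd
        label = universe.set_from_concentrations(c)
        counters[label.label] = counters.get(label.label, 0) + 1
        samples.append(
            OdorSample(
                f"{id_prefix}{label.label}-{counters[label.label]}",
                signal + noise,
                label=label,
                concentrations=np.array(c, dtype=float),
            )
        )
    return Dataset(universe, samples)


# ---------------------------------------------------------------------------
# bench-like preset

def bench_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Default configuration mirroring the reference bench: (M, E, A), m=8,
    near-collinear methanol/ethanol response columns."""
    universe = ComponentUniverse(("M", "E", "A"))
    cfg = GeneratorConfig(
        universe=universe,
        m=8,
        collinearity=Collinearity("M", "E"),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _bench_design(universe: ComponentUniverse) -> list[np.ndarray]:
    pures = make_design(universe, PURE_LEVELS, [universe.subset([n]) for n in universe.names])
    pairs = [s for s in universe.all_subsets() if len(s) == 2]
    doubles = make_design(universe, MIXTURE_LEVELS, pairs)
    triples = make_design(universe, MIXTURE_LEVELS, [universe.subset(universe.names)])
    return pures + doubles + triples  # 15 + 27 + 27 = 69 unique points


def generate_bench_datasets(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    n_samples: int = 133,
    n_train: int = 67,
) -> tuple[Dataset, Dataset]:
    """Simulate the full bench campaign and split it into train / test.

    The 69-point design (5 pure levels per component, all two- and
    three-component combinations of 34/51/68 ppm) is replicated until
    ``n_samples`` measurements exist, then randomly split (seeded
    permutation) into ``n_train`` training and the remaining test samples.
    """
    cfg = config if config is not None else bench_config(seed)
    panel = sample_panel(cfg)
    base = _bench_design(cfg.universe)
    reps = -(-n_samples // len(base))  # ceil
    design = (base * reps)[:n_samples]
    ds = generate_samples(panel, design, cfg)
    rng = np.random.default_rng(cfg.seed + 3)
    order = rng.permutation(len(ds))
    train = Dataset(cfg.universe, [ds.samples[i] for i in order[:n_train]])
    test = Dataset(cfg.universe, [ds.samples[i] for i in order[n_train:]])
    return train, test
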