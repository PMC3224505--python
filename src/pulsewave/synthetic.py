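"""Synthetic impulse-response data with planted ground truth.

Emulates the transcriptome of a nutrient-limited chemostat culture hit by an
impulse of the limiting nutrient: a 15-point sampling grid spanning the
pre-impulse steady state, 20/40/60 s, 8/16/24/32 min, 1-5 h, 7 h, and the
re-established steady state.  Genes follow one of six response archetypes
(immediate repression with recovery, delayed induction, sustained up/down,
damped oscillation, flat) grouped into planted co-expression modules, so
every downstream statistic can be checked against known structure.  A
matching stochastic-block interactome and planted term annotations complete
the trio of inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AnnotationTable, ExpressionSeries, InteractionNetwork, TimeGrid

__all__ = [
    "ArchetypeSpec",
    "ModuleSpec",
    "PlantedDesign",
    "default_time_grid",
    "default_design",
    "np_benchmark_design",
    "archetype_response",
    "simulate_expression",
    "simulate_network",
    "simulate_annotations",
    "BACKGROUND",
]

ARCHETYPES = (
    "immediate_down_recover",
    "delayed_up",
    "sustained_up",
    "sustained_down",
    "oscillatory",
    "flat",
)

#: Module label used for unplanted, flat background genes in truth tables.
BACKGROUND = "background"

#: The impulse perturbs expression for ~7 h at D = 0.1 h^-1; beyond this
#: horizon (i.e. at the second steady state) all archetypes sit at baseline.
IMPULSE_SPAN_S = 7 * 3600.0

_DILUTION_RATE_PER_H = 0.1


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parametrized temporal response shape, in log2 units around baseline.

    ``amplitude`` is the peak deviation (log2 fold change), ``onset`` the
    lag before a delayed response starts (delayed_up only; default two
    hours), ``recovery`` the exponential time constant of relaxation/rise,
    and ``period`` the oscillation period (oscillatory only).  All times in
    seconds.
    """

    kind: str
    amplitude: float = 2.0
    onset: float = 7200.0
    recovery: float = 1800.0
    period: float = 7200.0

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPES:
            raise ValueError(f"unknown archetype kind {self.kind!r}; expected one of {ARCHETYPES}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.recovery <= 0:
            raise ValueError("recovery time constant must be positive")
        if self.kind == "oscillatory" and self.period <= 0:
            raise ValueError("oscillatory archetype needs a positive period")


def archetype_response(spec: ArchetypeSpec, times_s) -> np.ndarray:
    """Noiseless log2 deviation from baseline at the given times (seconds).

    Responses are zero before the impulse (t < 0) and after the impulse
    horizon (t > ``IMPULSE_SPAN_S``), so every archetype has returned to
    baseline by the second steady state.  The sustained shapes rise with
    time constant ``recovery`` (transcript induction is not instantaneous)
    to a plateau held through the 7 h sample.
    """
    t = np.asarray(times_s, dtype=float)
    r = np.zeros_like(t)
    active = (t >= 0) & (t <= IMPULSE_SPAN_S)
    ta = t[active]
    a = spec.amplitude
    if spec.kind == "immediate_down_recover":
        r[active] = -a * np.exp(-ta / spec.recovery)
    elif spec.kind == "delayed_up":
        rise = np.clip(ta - spec.onset, 0.0, None)
        r[active] = np.where(ta >= spec.onset, a * (1.0 - np.exp(-rise / spec.recovery)), 0.0)
    elif spec.kind == "sustained_up":
        r[active] = a * (1.0 - np.exp(-ta / spec.recovery))
    elif spec.kind == "sustained_down":
        r[active] = -a * (1.0 - np.exp(-ta / spec.recovery))
    elif spec.kind == "oscillatory":
        damp = np.exp(-_DILUTION_RATE_PER_H * ta / 3600.0)
        r[active] = a * np.sin(2.0 * np.pi * ta / spec.period) * damp
    # flat: zeros
    return r


@dataclass(frozen=True)
class ModuleSpec:
    """A planted module: ``size`` genes sharing one archetype.

    ``signs`` is either a scalar +1/-1 applied to every member or a
    per-gene sequence; mixed signs plant exactly anti-correlated pairs
    inside the module.
    """

    size: int
    archetype: ArchetypeSpec
    signs: object = 1

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        object.__setattr__(self, "signs", self._expand_signs())

    def _expand_signs(self) -> tuple[int, ...]:
        s = self.signs
        if isinstance(s, (int, float, np.integer, np.floating)):
            s = [int(s)] * self.size
        s = tuple(int(x) for x in s)
        if len(s) != self.size or any(x not in (-1, 1) for x in s):
            raise ValueError("signs must be +/-1, scalar or one per gene")
        return s


@dataclass(frozen=True)
class PlantedDesign:
    """Full specification of a synthetic experiment."""

    modules: tuple[ModuleSpec, ...]
    noise_sd: float = 0.1
    seed: int = 0
    n_background_flat: int = 0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", tuple(self.modules))
        if not self.modules and self.n_background_flat == 0:
            raise ValueError("design is empty: no modules and no background genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_background_flat < 0:
            raise ValueError("n_background_flat must be non-negative")

    @property
    def n_genes(self) -> int:
        return sum(m.size for m in self.modules) + self.n_background_flat


def default_time_grid(second_steady_hours: float = 100.0) -> TimeGrid:
    """The 15-sample impulse design: pre-impulse steady state (-1 s by
    convention), 20/40/60 s, 8/16/24/32 min, 1/2/3/4/5/7 h, and the second
    steady state once the culture has re-equilibrated (nominally 100 h)."""
    times = [-1.0, 20.0, 40.0, 60.0, 480.0, 960.0, 1440.0, 1920.0,
             3600.0, 7200.0, 10800.0, 14400.0, 18000.0, 25200.0,
             second_steady_hours * 3600.0]
    labels = ("ss1", "20s", "40s", "60s", "8min", "16min", "24min", "32min",
              "1h", "2h", "3h", "4h", "5h", "7h", "ss2")
    steady = [True] + [False] * 13 + [True]
    return TimeGrid(np.array(times), labels, np.array(steady), reference_index=0)


def default_design(seed: int = 0) -> PlantedDesign:
    """Impulse-response design emulating the archetype mix of a glucose
    perturbation: immediate repression of respiratory/carboxylic-acid-like
    genes, delayed induction of glycolysis-like genes, sustained up/down
    groups, a damped oscillatory group, and flat background."""
    modules = (
        ModuleSpec(60, ArchetypeSpec("immediate_down_recover", amplitude=2.0, recovery=1800.0)),
        ModuleSpec(50, ArchetypeSpec("delayed_up", amplitude=2.0, onset=7200.0, recovery=3600.0)),
        ModuleSpec(40, ArchetypeSpec("sustained_up", amplitude=1.5)),
        ModuleSpec(40, ArchetypeSpec("sustained_down", amplitude=1.5)),
        ModuleSpec(30, ArchetypeSpec("oscillatory", amplitude=1.5, period=7200.0)),
    )
    return PlantedDesign(modules=modules, noise_sd=0.1, seed=seed, n_background_flat=200)


def np_benchmark_design(seed: int, noise_sd: float = 0.15) -> PlantedDesign:
    """Planted benchmark for NP module recovery: 2-4 modules of 50-125 genes.

    Modules cycle through sustained_up with signs +/- and oscillatory with
    signs +/-, so every module pair is either exactly anti-correlated or
    essentially uncorrelated (|PCC| < 0.05) — the regime in which network
    modules are identifiable from the |PCC| >= 0.7 reduction.  The module
    count (2, 3 or 4) and sizes derive from the seed.
    """
    arch = (
        ("sustained_up", 1),
        ("sustained_up", -1),
        ("oscillatory", 1),
        ("oscillatory", -1),
    )
    rng = np.random.default_rng(seed)
    k = 2 + seed % 3
    sizes = rng.integers(50, 126, size=k)
    modules = tuple(
        ModuleSpec(int(sz), ArchetypeSpec(kind), signs=sign)
        for sz, (kind, sign) in zip(sizes, arch[:k])
    )
    return PlantedDesign(modules=modules, noise_sd=noise_sd, seed=seed)


def simulate_expression(design: PlantedDesign, grid: TimeGrid):
    """Generate a log2 expression matrix with planted archetypes.

    Returns ``(ExpressionSeries, truth)`` where ``truth`` is a DataFrame
    with columns ``gene_id, module, archetype, sign``; background genes
    carry module label :data:`BACKGROUND`.  Identical seeds give identical
    output.
    """
    rng = np.random.default_rng(design.seed)
    gene_ids: list[str] = []
    profiles: list[np.ndarray] = []
    records: list[tuple[str, str, str, int]] = []
    for mi, mod in enumerate(design.modules, start=1):
        label = f"M{mi}"
        shape = archetype_response(mod.archetype, grid.times)
        for gi in range(mod.size):
            gid = f"{label}_{gi:03d}"
            gene_ids.append(gid)
            profiles.append(mod.signs[gi] * shape)
            records.append((gid, label, mod.archetype.kind, mod.signs[gi]))
    for gi in range(design.n_background_flat):
        gid = f"BG_{gi:03d}"
        gene_ids.append(gid)
        profiles.append(np.zeros(len(grid)))
        records.append((gid, BACKGROUND, "flat", 1))

    signal = np.vstack(profiles)
    baselines = rng.normal(design.baseline_mean, design.baseline_sd, size=len(gene_ids))
    values = baselines[:, None] + signal
    if design.noise_sd > 0:
        values = values + rng.normal(0.0, design.noise_sd, size=values.shape)
    expr = ExpressionSeries(tuple(gene_ids), values, grid)
    truth = pd.DataFrame(records, columns=["gene_id", "module", "archetype", "sign"])
    return expr, truth


def simulate_network(
    truth: pd.DataFrame,
    p_intra: float,
    p_inter: float,
    n_tf: int = 0,
    seed: int = 0,
    n_targets_per_tf: int = 5,
) -> InteractionNetwork:
    """Stochastic-block interactome over the genes of a planted design.

    Within-module gene pairs receive an undirected PPI edge with probability
    ``p_intra``, all other pairs (including pairs touching background genes)
    with ``p_inter``.  ``n_tf`` genes are flagged as transcription factors
    and given directed PDI edges to ``n_targets_per_tf`` sampled targets.
    """
    if not (0.0 <= p_inter <= p_intra <= 1.0):
        raise ValueError("need 0 <= p_inter <= p_intra <= 1")
    genes = truth["gene_id"].tolist()
    modules = truth["module"].to_numpy()
    n = len(genes)
    if n_tf < 0 or n_tf > n:
        raise ValueError("n_tf must be between 0 and the number of genes")
    rng = np.random.default_rng(seed)

    iu, ju = np.triu_indices(n, k=1)
    same = (modules[iu] == modules[ju]) & (modules[iu] != BACKGROUND)
    p = np.where(same, p_intra, p_inter)
    keep = rng.random(len(iu)) < p
    edges = [(genes[i], genes[j], "PPI") for i, j in zip(iu[keep], ju[keep])]

    tf_set: set[str] = set()
    if n_tf:
        tfs = rng.choice(n, size=n_tf, replace=False)
        pdi_seen = set()
        for ti in tfs:
            tf = genes[ti]
            tf_set.add(tf)
            candidates = np.delete(np.arange(n), ti)
            k = min(n_targets_per_tf, len(candidates))
            for tj in rng.choice(candidates, size=k, replace=False):
                key = (tf, genes[tj])
                if key not in pdi_seen:
                    pdi_seen.add(key)
                    edges.append((tf, genes[tj], "PDI"))
    return InteractionNetwork(tuple(genes), tuple(edges), frozenset(tf_set))


def simulate_annotations(
    truth: pd.DataFrame,
    enriched_term_per_module: dict | None = None,
    frac_in: float = 0.8,
    frac_bg: float = 0.05,
    seed: int = 0,
) -> AnnotationTable:
    """Plant one enriched term per module.

    Module members receive their module's term with probability ``frac_in``;
    every other gene receives it with ``frac_bg``.
    """
    if not (0.0 <= frac_bg <= frac_in <= 1.0):
        raise ValueError("need 0 <= frac_bg <= frac_in <= 1")
    rng = np.random.default_rng(seed)
    genes = truth["gene_id"].to_numpy()
    modules = truth["module"].to_numpy()
    module_labels = [m for m in pd.unique(modules) if m != BACKGROUND]
    if enriched_term_per_module is None:
        enriched_term_per_module = {m: f"TERM_{m}" for m in module_labels}
    pairs: list[tuple[str, str]] = []
    names: dict[str, str] = {}
    for m in module_labels:
        term = enriched_term_per_module[m]
        names[term] = f"planted term for module {m}"
        member = modules == m
        p = np.where(member, frac_in, frac_bg)
        hit = rng.random(len(genes)) < p
        pairs.extend((g, term) for g in genes[hit])
    return AnnotationTable(tuple(pairs), names)
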