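"""Seeded synthetic fermentation datasets with known ground truth.

The generator emulates the statistical structure of an indigo-reduction
fermentation time series at the count-table level (no read simulation):

* guilds of taxa follow logistic latent trajectories (decliners, early
  and late risers, stable taxa) over the sampling days; the remaining
  compositional mass is spread over a large set of rare background taxa;
* per-sample compositions are the day's latent composition perturbed by
  Dirichlet noise (concentration = ``noise_dispersion`` x composition)
  and counted multinomially at fixed depth, so replicates of a day share
  one latent state and differ only by sampling noise;
* the ORP trajectory follows the batch scenario: ``fast_drop`` (big
  batch, at or below -600 mV from the start) or ``slow_drop`` (small
  batch, above -400 mV on the first sampling day, below about -598 mV
  from roughly day 5);
* dyeing intensity is a Hill-type saturating function of the summed
  riser ("reducer") guild fraction, gated off while ORP is above
  -550 mV, plus Gaussian noise;
* genome content plants ``n_signal_functions`` gene families with
  elevated copy number in reducer-guild taxa; background families are
  either uniform-copy core functions or accessory functions enriched in
  non-reducer taxa. The truth record lists what was planted where.

The same seed always yields a bit-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables_io
from .errors import InputError

TRAJECTORY_KINDS = ("decliner", "early_riser", "late_riser", "stable")
RISER_KINDS = ("early_riser", "late_riser")
ORP_SCENARIOS = ("fast_drop", "slow_drop")

#: Subpathway labels carrying the planted signal functions.
SIGNAL_SUBPATHWAYS = (
    "Prokaryotic defense system",
    "Starch and sucrose metabolism",
    "Replication, recombination and repair proteins",
)
BACKGROUND_SUBPATHWAYS = (
    "Glycolysis / Gluconeogenesis",
    "ABC transporters",
    "Ribosome",
    "Purine metabolism",
    "Two-component system",
    "Oxidative phosphorylation",
    "Amino sugar and nucleotide sugar metabolism",
    "Peptidoglycan biosynthesis",
)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class GuildSpec:
    """A set of taxa sharing one latent trajectory.

    ``members`` are taxon labels of the form ``Genus_k``; the genus is
    the label up to the final underscore. Members split the guild's
    fraction equally.
    """

    name: str
    members: tuple[str, ...]
    trajectory_kind: str
    growth_rate: float
    midpoint_day: float
    baseline_fraction: float
    asymptote_fraction: float

    def __post_init__(self):
        if self.trajectory_kind not in TRAJECTORY_KINDS:
            raise InputError(f"unknown trajectory kind {self.trajectory_kind!r}")
        if not self.members:
            raise InputError(f"guild {self.name!r} has no members")
        if not np.isfinite(self.growth_rate):
            raise InputError(f"guild {self.name!r}: growth_rate must be finite")
        if self.midpoint_day < 0:
            raise InputError(f"guild {self.name!r}: midpoint_day must be >= 0")
        for frac in (self.baseline_fraction, self.asymptote_fraction):
            if not (0.0 <= frac <= 1.0):
                raise InputError(f"guild {self.name!r}: fractions must lie in [0, 1]")
        if self.trajectory_kind == "decliner" and self.asymptote_fraction > self.baseline_fraction:
            raise InputError(f"decliner guild {self.name!r} must decay")
        if self.trajectory_kind in RISER_KINDS and self.asymptote_fraction < self.baseline_fraction:
            raise InputError(f"riser guild {self.name!r} must rise")


def guild_trajectory(spec: GuildSpec, days) -> np.ndarray:
    """Latent guild fraction at each sampling day.

    Stable guilds stay at their baseline; risers and decliners follow a
    logistic between baseline and asymptote with half-maximal change at
    ``midpoint_day``.
    """
    days = np.asarray(days, dtype=float)
    if days.size == 0:
        raise InputError("empty day list")
    if days.ndim != 1 or (np.diff(days) <= 0).any():
        raise InputError("days must be a strictly increasing 1-D sequence")
    if spec.trajectory_kind == "stable":
        return np.full(days.shape, spec.baseline_fraction)
    span = spec.asymptote_fraction - spec.baseline_fraction
    with np.errstate(over="ignore"):
        frac = spec.baseline_fraction + span * _sigmoid(
            spec.growth_rate * (days - spec.midpoint_day))
    return np.clip(frac, 0.0, 1.0)


def genus_of_member(member: str) -> str:
    """Genus of a ``Genus_k`` member label."""
    return member.rsplit("_", 1)[0] if "_" in member else member


def default_guilds(orp_scenario: str) -> tuple[GuildSpec, ...]:
    """Guild sets encoding the two batch designs.

    ``fast_drop`` (big batch): the community has already converged to
    the reducing state at first sampling — reducer guilds carry nearly
    all visible mass, aerobes/Actinomycetota linger only as rare taxa.
    ``slow_drop`` (small batch): aerobic decliners start abundant and
    are replaced by early then late risers over the first weeks.
    """
    if orp_scenario == "fast_drop":
        return (
            GuildSpec("early_reducers",
                      ("Alkalibacterium_1", "Alkalibacterium_2", "Alkalicella_1"),
                      "early_riser", 0.6, 4.0, 0.20, 0.50),
            GuildSpec("late_reducers",
                      ("Tissierella_1", "Amphibacillus_1", "Enterococcus_1",
                       "Alkaliphilus_1"),
                      "late_riser", 0.25, 16.0, 0.01, 0.28),
            GuildSpec("actino_decliners",
                      ("Stackebrandtia_1", "Streptomyces_1", "Glycomyces_1",
                       "Georgenia_1", "Nocardiopsis_1", "Microbacterium_1"),
                      "decliner", 1.2, 1.5, 0.012, 0.0006),
        )
    if orp_scenario == "slow_drop":
        return (
            GuildSpec("aerobe_decliners",
                      ("Bacillus_1", "Stackebrandtia_1", "Streptomyces_1",
                       "Glycomyces_1"),
                      "decliner", 0.9, 4.5, 0.28, 0.01),
            GuildSpec("early_reducers",
                      ("Alkalicella_1", "Alkalibacterium_1", "Enterococcus_1"),
                      "early_riser", 1.1, 4.8, 0.004, 0.48),
            GuildSpec("late_reducers",
                      ("Amphibacillus_1", "Tissierella_1"),
                      "late_riser", 0.2, 18.0, 0.004, 0.20),
        )
    raise InputError(f"unknown ORP scenario {orp_scenario!r}")


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults mirror the two batch designs."""

    days: tuple[int, ...] = (3, 10, 27, 212)
    replicates_per_day: int = 2
    depth: int = 20000
    n_functions: int = 150
    n_signal_functions: int = 25
    orp_scenario: str = "fast_drop"
    #: Dirichlet concentration scalar; replicates are duplicate aliquots
    #: of one stirred vat, so within-day variability is modest. The true
    #: replicate variability of such ferments is not well characterised;
    #: this default is a stated guess. ``inf`` disables the noise.
    noise_dispersion: float = 2000.0
    seed: int = 0
    guilds: tuple[GuildSpec, ...] | None = None
    n_background_taxa: int = 80
    # dyeing-intensity generative law (Hill in reducer fraction, ORP-gated)
    intensity_max: float = 2.8
    hill_k: float = 0.55
    hill_coefficient: float = 3.0
    intensity_floor: float = 0.45
    intensity_noise_sd: float = 0.08
    orp_gate_mV: float = -550.0
    # genome content
    signal_extra_copies: int = 5
    background_copies: int = 1

    def __post_init__(self):
        if self.depth <= 0:
            raise InputError("depth must be positive")
        if self.orp_scenario not in ORP_SCENARIOS:
            raise InputError(f"unknown ORP scenario {self.orp_scenario!r}")
        days = np.asarray(self.days)
        if days.size == 0 or (np.diff(days) <= 0).any():
            raise InputError("days must be nonempty and strictly increasing")
        if self.n_signal_functions > self.n_functions:
            raise InputError("n_signal_functions cannot exceed n_functions")
        if self.replicates_per_day < 1:
            raise InputError("replicates_per_day must be >= 1")
        if self.guilds is None:
            self.guilds = default_guilds(self.orp_scenario)
        if not self.guilds:
            raise InputError("empty guild set")
        base_sum = sum(g.baseline_fraction for g in self.guilds)
        if base_sum > 1.0 + 1e-9:
            raise InputError(
                f"guild baseline fractions sum to {base_sum:.3f} > 1")

    @classmethod
    def big_batch(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Big 270 L batch: 4 sampling days x 2 replicates, fast ORP drop."""
        kw = dict(days=(3, 10, 27, 212), orp_scenario="fast_drop",
                  depth=20000, seed=seed)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def small_batch(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Small 5 L batch: 8 sampling days, slow ORP drop."""
        kw = dict(days=(2, 5, 6, 7, 14, 29, 96, 200), orp_scenario="slow_drop",
                  depth=14500, seed=seed)
        kw.update(overrides)
        return cls(**kw)

    @property
    def batch_label(self) -> str:
        return "big" if self.orp_scenario == "fast_drop" else "small"


def orp_trajectory(days, orp_scenario: str) -> np.ndarray:
    """Deterministic ORP (mV) at each day for a batch scenario."""
    d = np.asarray(days, dtype=float)
    if orp_scenario == "fast_drop":
        return -640.0 + 40.0 * _sigmoid(0.02 * (d - 100.0))
    if orp_scenario == "slow_drop":
        return (-350.0 - 280.0 * _sigmoid(2.0 * (d - 3.4))
                + 55.0 * _sigmoid(0.04 * (d - 60.0)))
    raise InputError(f"unknown ORP scenario {orp_scenario!r}")


def ph_trajectory(days, orp_scenario: str) -> np.ndarray:
    """Deterministic pH at each day (slow alkaline decline with age)."""
    d = np.asarray(days, dtype=float)
    base = 10.5 if orp_scenario == "fast_drop" else 10.6
    return base - 0.3 * _sigmoid(0.02 * (d - 30.0))


def intensity_law(reducer_fraction, orp_mV, config: SyntheticConfig) -> np.ndarray:
    """Noise-free dyeing intensity: ORP-gated Hill response."""
    f = np.asarray(reducer_fraction, dtype=float)
    gate = np.asarray(orp_mV, dtype=float) <= config.orp_gate_mV
    h = config.hill_coefficient
    hill = f ** h / (config.hill_k ** h + f ** h)
    return config.intensity_floor + config.intensity_max * hill * gate


@dataclass
class SyntheticDataset:
    """One simulated fermentation with its complete ground truth."""

    config: SyntheticConfig
    counts: pd.DataFrame                  # taxon x sample integer counts
    metadata: pd.DataFrame                # per-sample day/batch/pH/ORP/intensity
    taxonomy: dict[str, str]              # taxon -> lineage
    genome_content: pd.DataFrame          # taxon x function copy numbers
    function_table: pd.DataFrame          # function x sample abundances
    stratified: pd.DataFrame              # PICRUSt2-legacy contribution rows
    hierarchy: pd.DataFrame               # function -> subpathway map
    truth: dict = field(default_factory=dict)

    def to_dir(self, path) -> None:
        """Write every table in its pipeline dialect."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        tables_io.write_count_table(self.counts, path / "counts.tsv")
        tables_io.write_metadata(self.metadata, path / "metadata.tsv")
        tables_io.write_taxonomy(self.taxonomy, path / "taxonomy.tsv")
        tables_io.write_function_table(self.function_table, path / "functions.tsv")
        tables_io.write_stratified(self.stratified, path / "stratified.tsv")
        tables_io.write_hierarchy(self.hierarchy, path / "hierarchy.tsv")
        tables_io.write_count_table(self.genome_content.T, path / "genome_content.tsv")


def _latent_composition(config: SyntheticConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-taxon latent fractions for each day, plus taxon -> guild map."""
    days = np.asarray(config.days, dtype=float)
    frames = {}
    guild_of: dict[str, str] = {}
    for guild in config.guilds:
        frac = guild_trajectory(guild, days)
        share = frac / len(guild.members)
        for member in guild.members:
            frames[member] = share
            guild_of[member] = guild.name
    latent = pd.DataFrame(frames, index=config.days).T
    residual = 1.0 - latent.sum(axis=0).to_numpy()
    if (residual < -1e-9).any():
        raise InputError("guild fractions exceed 1 on some day")
    residual = np.clip(residual, 0.0, 1.0)
    if config.n_background_taxa > 0:
        bkg = pd.DataFrame(
            np.tile(residual / config.n_background_taxa,
                    (config.n_background_taxa, 1)),
            index=[f"Background{i:03d}_1" for i in range(config.n_background_taxa)],
            columns=config.days,
        )
        for taxon in bkg.index:
            guild_of[taxon] = "background"
        latent = pd.concat([latent, bkg])
    elif (residual > 1e-9).any():
        raise InputError(
            "guild fractions do not sum to 1 and n_background_taxa is 0")
    return latent, guild_of


def _lineage(member: str) -> str:
    genus = genus_of_member(member)
    return f"d__Bacteria;p__Synthetica;c__;o__;f__;g__{genus}"


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one complete dataset under ``config`` (bit-stable per seed)."""
    ss = np.random.SeedSequence(config.seed)
    rng_counts, rng_genome, rng_pheno = (
        np.random.default_rng(child) for child in ss.spawn(3))

    latent, guild_of = _latent_composition(config)
    taxa = list(latent.index)
    taxonomy = {t: _lineage(t) for t in taxa}
    reducer_guilds = {g.name for g in config.guilds
                      if g.trajectory_kind in RISER_KINDS}
    reducer_taxa = [t for t in taxa if guild_of[t] in reducer_guilds]

    # --- counts -----------------------------------------------------------
    sample_ids, sample_days = [], []
    counts = {}
    for day in config.days:
        x = np.clip(latent[day].to_numpy(), 1e-9, None)
        x = x / x.sum()
        for rep in range(1, config.replicates_per_day + 1):
            sid = f"{config.batch_label}D{day:03d}R{rep}"
            if np.isinf(config.noise_dispersion):
                p = x
            else:
                p = rng_counts.dirichlet(config.noise_dispersion * x)
            counts[sid] = rng_counts.multinomial(config.depth, p)
            sample_ids.append(sid)
            sample_days.append(day)
    count_table = pd.DataFrame(counts, index=taxa)
    count_table.index.name = "taxon_id"

    # --- genome content ---------------------------------------------------
    function_ids = [f"K{i + 1:05d}" for i in range(config.n_functions)]
    signal_functions = sorted(
        rng_genome.choice(function_ids, size=config.n_signal_functions,
                          replace=False))
    background_functions = [f for f in function_ids if f not in set(signal_functions)]
    non_reducers = [t for t in taxa if t not in set(reducer_taxa)]

    genome = pd.DataFrame(config.background_copies, index=taxa,
                          columns=function_ids, dtype=np.int64)
    for fn in background_functions:
        if rng_genome.random() < 0.4 and len(non_reducers) >= 5:
            # accessory function of the non-reducer flora
            carriers = rng_genome.choice(non_reducers, size=5, replace=False)
            genome.loc[carriers, fn] += 2
        elif rng_genome.random() < 0.5:
            genome[fn] += 1  # two-copy core function
    for fn in signal_functions:
        genome.loc[reducer_taxa, fn] += config.signal_extra_copies
    genome.index.name = "taxon_id"

    # --- predicted function tables ---------------------------------------
    function_table = genome.T @ count_table
    function_table.index.name = "function_id"

    strat_rows = []
    for sid in sample_ids:
        col = count_table[sid]
        present = col[col > 0]
        for taxon, abundance in present.items():
            copies = genome.loc[taxon]
            nz = copies[copies > 0]
            for fn, cpg in nz.items():
                strat_rows.append((sid, fn, taxon, int(cpg), int(abundance),
                                   int(cpg) * int(abundance)))
    stratified = pd.DataFrame(strat_rows, columns=list(tables_io.STRATIFIED_COLUMNS))
    stratified["taxon"] = [tables_io.genus_of(taxonomy[o])
                           for o in stratified["OTU"]]

    # --- hierarchy --------------------------------------------------------
    hier_rows = []
    for i, fn in enumerate(signal_functions):
        sub = SIGNAL_SUBPATHWAYS[i % len(SIGNAL_SUBPATHWAYS)]
        hier_rows.append((fn, sub, "Signal superpathway", "Metabolism"))
    for i, fn in enumerate(background_functions):
        sub = BACKGROUND_SUBPATHWAYS[i % len(BACKGROUND_SUBPATHWAYS)]
        hier_rows.append((fn, sub, "Background superpathway", "Metabolism"))
    hierarchy = (pd.DataFrame(hier_rows,
                              columns=["function_id", "subpathway",
                                       "superpathway", "category"])
                 .set_index("function_id").sort_index())

    # --- phenotype --------------------------------------------------------
    day_arr = np.asarray(config.days, dtype=float)
    orp_by_day = dict(zip(config.days, orp_trajectory(day_arr, config.orp_scenario)))
    ph_by_day = dict(zip(config.days, ph_trajectory(day_arr, config.orp_scenario)))
    reducer_frac_by_day = latent.loc[reducer_taxa].sum(axis=0) if reducer_taxa else (
        pd.Series(0.0, index=list(config.days)))
    meta_rows = []
    for sid, day in zip(sample_ids, sample_days):
        clean = float(intensity_law(reducer_frac_by_day[day], orp_by_day[day], config))
        noisy = max(0.0, clean + rng_pheno.normal(0.0, config.intensity_noise_sd))
        rep = sid.rsplit("R", 1)[1]
        meta_rows.append({
            "sample_id": sid, "day": int(day), "batch": config.batch_label,
            "replicate": f"R{rep}", "pH": round(float(ph_by_day[day]), 3),
            "orp_mV": round(float(orp_by_day[day]), 1),
            "dyeing_intensity": round(noisy, 4),
        })
    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)

    truth = {
        "signal_functions": list(signal_functions),
        "background_functions": list(background_functions),
        "reducer_taxa": list(reducer_taxa),
        "guild_of": dict(guild_of),
        "latent_composition": latent,
        "reducer_fraction": reducer_frac_by_day,
        "orp_by_day": orp_by_day,
    }
    return SyntheticDataset(
        config=config, counts=count_table, metadata=metadata,
        taxonomy=taxonomy, genome_content=genome,
        function_table=function_table.astype(float), stratified=stratified,
        hierarchy=hierarchy, truth=truth,
    )
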