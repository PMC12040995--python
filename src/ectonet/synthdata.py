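"""Synthetic host-parasite collections with controllable sex effects.

The generator emulates the structure of a field survey of small mammals and
their ectoparasites: several host species sampled in one or more regions,
two parasite groups (fleas and mites), overdispersed per-host parasite
loads, and a few-common/many-rare parasite community.  Per host, the total
load is negative-binomial (mean multiplied by ``male_abundance_mult`` for
males) and is allocated over parasite species by a multinomial whose
probabilities follow a geometric rank-abundance curve, perturbed per sex by
a Dirichlet draw whose divergence is set by ``male_composition_shift``
(0 = identical compositions in the two sexes).  Unparasitized hosts are
redrawn so every network holds exactly ``hosts_per_sex`` parasitized
females and males.  The true per-species effects are recorded alongside the
data for recovery tests.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from dendropy.simulate import treesim

from ectonet.netcore import HostRecord, InteractionMatrix, NetworkBundle, write_records

PARASITE_GROUPS = ("flea", "mite")


@dataclass
class SimulationConfig:
    n_species: int = 21
    hosts_per_sex: int = 25
    n_parasites: int = 12
    nb_mean: float = 8.0
    nb_dispersion: float = 1.0  # gamma-shape; smaller = more overdispersed
    male_abundance_mult: float = 1.0
    male_composition_shift: float = 0.0
    parasite_prevalence_decay: float = 0.75  # geometric rank-abundance ratio
    regions: tuple[str, ...] = ("north",)
    seed: int = 0
    # optional per-species ranges; scalars above are used when None
    abundance_mult_range: tuple[float, float] | None = None
    composition_shift_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be > 0")
        if self.male_abundance_mult <= 0:
            raise ValueError("male_abundance_mult must be > 0")
        if self.male_composition_shift < 0:
            raise ValueError("male_composition_shift must be >= 0")
        if not 0 < self.parasite_prevalence_decay <= 1:
            raise ValueError("parasite_prevalence_decay must be in (0, 1]")
        if self.n_parasites < 2 or self.hosts_per_sex < 2:
            raise ValueError("need >=2 parasite species and >=2 hosts per sex")


@dataclass
class TruthRecord:
    """Ground truth stored beside generated data, for recovery tests."""

    species_effects: dict = field(default_factory=dict)
    newick: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {"species_effects": self.species_effects, "newick": self.newick}, indent=2
        )


def _rank_abundance(n_parasites: int, decay: float) -> np.ndarray:
    p = decay ** np.arange(n_parasites)
    return p / p.sum()


def _sex_preferences(
    base: np.ndarray, shift: float, rng: np.random.Generator
) -> np.ndarray:
    """One Dirichlet-perturbed preference vector; returns base when shift=0."""
    if shift == 0:
        return base
    alpha = base / shift
    return rng.dirichlet(np.maximum(alpha, 1e-6))


def _draw_parasitized_loads(
    n: int, mean: float, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """n negative-binomial loads conditioned on being >= 1 (zero-load hosts
    are redrawn, emulating the exclusion of unparasitized individuals)."""
    p_zero = (dispersion / (dispersion + mean)) ** dispersion
    if 1.0 - p_zero < 0.05:
        raise ValueError(
            f"infeasible config: P(parasitized) = {1 - p_zero:.3f} < 0.05 "
            f"(nb_mean={mean}, dispersion={dispersion})"
        )
    loads = np.empty(n, dtype=np.int64)
    filled = 0
    attempts = 0
    while filled < n:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("could not draw enough parasitized hosts")
        lam = rng.gamma(dispersion, mean / dispersion, size=2 * (n - filled) + 8)
        draw = rng.poisson(lam)
        draw = draw[draw > 0][: n - filled]
        loads[filled : filled + len(draw)] = draw
        filled += len(draw)
    return loads


def simulate_network(
    config: SimulationConfig,
    species_label: str,
    rng: np.random.Generator,
    region: str | None = None,
    parasite_group: str = "flea",
    abundance_mult: float | None = None,
    composition_shift: float | None = None,
) -> tuple[NetworkBundle, TruthRecord]:
    """Simulate one individual-based network for one host species."""
    region = region if region is not None else config.regions[0]
    mult = abundance_mult if abundance_mult is not None else config.male_abundance_mult
    shift = (
        composition_shift
        if composition_shift is not None
        else config.male_composition_shift
    )
    base = _rank_abundance(config.n_parasites, config.parasite_prevalence_decay)
    pref = {
        "F": _sex_preferences(base, shift, rng),
        "M": _sex_preferences(base, shift, rng),
    }
    n = config.hosts_per_sex
    parasites = [f"{parasite_group}_sp{j + 1:02d}" for j in range(config.n_parasites)]
    rows, hosts = [], []
    for sex, mean in (("F", config.nb_mean), ("M", config.nb_mean * mult)):
        loads = _draw_parasitized_loads(n, mean, config.nb_dispersion, rng)
        counts = rng.multinomial(loads, pref[sex][None, :].repeat(n, axis=0))
        for i in range(n):
            host_id = f"{species_label}|{region}|{parasite_group}|{sex}{i + 1:03d}"
            hosts.append(
                HostRecord(
                    host_id=host_id,
                    species=species_label,
                    region=region,
                    site="site1",
                    sex=sex,
                )
            )
            rows.append(counts[i])
    mat = np.vstack(rows)
    # drop parasite species never observed in this network
    keep = mat.sum(axis=0) > 0
    # a multinomial row can be all-zero only if the load was 0, which cannot
    # happen here (loads >= 1)
    matrix = InteractionMatrix(
        mat[:, keep], [h.host_id for h in hosts], [p for p, k in zip(parasites, keep) if k]
    )
    bundle = NetworkBundle(
        matrix=matrix,
        hosts=hosts,
        parasite_group=parasite_group,
        id=f"{species_label}|{region}|{parasite_group}",
    )
    truth = TruthRecord(
        species_effects={
            species_label: {"abundance_mult": mult, "composition_shift": shift}
        }
    )
    return bundle, truth


def yule_tree(species: list[str], seed: int) -> dendropy.Tree:
    """Pure-birth random tree over the given species labels."""
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=len(species),
        rng=random.Random(seed),
    )
    for leaf, label in zip(tree.leaf_node_iter(), species):
        leaf.taxon.label = label
    return tree


def simulate_collection(
    config: SimulationConfig,
) -> tuple[list[NetworkBundle], dendropy.Tree, TruthRecord]:
    """One bundle per species x region x parasite group, plus a Yule tree."""
    if config.n_species < 2:
        raise ValueError("need at least 2 host species")
    rng = np.random.default_rng(config.seed)
    species = [f"species{i + 1:02d}" for i in range(config.n_species)]
    truth = TruthRecord()
    bundles = []
    for sp in species:
        if config.abundance_mult_range is not None:
            lo, hi = config.abundance_mult_range
            mult = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            mult = config.male_abundance_mult
        if config.composition_shift_range is not None:
            shift = float(rng.uniform(*config.composition_shift_range))
        else:
            shift = config.male_composition_shift
        truth.species_effects[sp] = {
            "abundance_mult": mult,
            "composition_shift": shift,
        }
        for region in config.regions:
            for group in PARASITE_GROUPS:
                bundle, _ = simulate_network(
                    config, sp, rng, region=region, parasite_group=group,
                    abundance_mult=mult, composition_shift=shift,
                )
                bundles.append(bundle)
    tree = yule_tree(species, seed=config.seed)
    truth.newick = tree.as_string(schema="newick").strip()
    return bundles, tree, truth


def write_collection(
    bundles: list[NetworkBundle],
    tree: dendropy.Tree,
    truth: TruthRecord,
    outdir: str | Path,
) -> None:
    """Write the long-format CSV, the Newick tree and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records: list[HostRecord] = []
    triples = []
    for b in bundles:
        records.extend(b.hosts)
        for i, host in enumerate(b.matrix.host_ids):
            for j, parasite in enumerate(b.matrix.parasites):
                c = int(b.matrix.counts[i, j])
                if c > 0:
                    triples.append((host, b.parasite_group, parasite, c))
    write_records(outdir / "records.csv", records, triples)
    tree.write(path=str(outdir / "hosts.nwk"), schema="newick")
    (outdir / "truth.json").write_text(truth.to_json())
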