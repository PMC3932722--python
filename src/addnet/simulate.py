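"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates, without any external download:

* a bipartite drug-target network whose drug degrees follow a truncated
  discrete power law on {1..20} with an independent zero-target coin
  (three of the 44 reference drugs have no target, hence the default
  zero probability of 3/44);
* category structure — addictive drugs are partitioned into six action
  categories, each drawing most of its targets from a preferred target
  block, so category clustering is recoverable downstream;
* a surrounding non-addictive drug pool whose targets come from the
  addictive target universe plus a private gene pool, so that only some
  pool drugs qualify for network expansion;
* ATC-style classification letters, with the addictive group heavily
  skewed toward the nervous-system class;
* pathway-style gene sets with planted enriched sets; and
* PubMed-style count triples, hypergeometric under the null so the
  downstream Fisher screen is exactly calibrated, with planted drugs
  inflated to a configurable observed/expected ratio.

Every generator is deterministic under a fixed seed; the three
generators draw from independent seed-derived streams so they can be
called in any order or in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import (
    NIDA_CATEGORIES,
    NIDA_NONE,
    PUBMED_2012_TOTAL,
    DrugRecord,
    GeneSetCollection,
    LiteratureCountRow,
    LiteratureCountTable,
    TargetRecord,
)

#: Reference category sizes for the six addictive-drug action classes
#: (depressants, dissociative anesthetics, hallucinogens, opioids and
#: morphine derivatives, stimulants, other compounds).
CATEGORY_WEIGHTS = (12, 2, 1, 10, 6, 13)

MAX_DRUG_DEGREE = 20

#: ATC anatomical main group letters.
ATC_LETTERS = "ABCDGHJLMNPRSV"


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_addictive: int = 44
    n_nonaddictive_pool: int = 1500
    n_targets: int = 91
    drug_degree_gamma: float = 2.2
    p_zero_target: float = 3 / 44
    n_categories: int = 6
    category_cohesion: float = 0.8
    n_gene_sets: int = 50
    planted_enriched_sets: int = 3
    corpus_total: int = PUBMED_2012_TOTAL
    baseline_cooccurrence_rate: float = 1.0
    planted_assoc_drugs: int = 10
    planted_assoc_ratio: float = 10.0
    universe_size: int = 2000
    keyword_abstracts: int = 200_000

    def validate(self) -> None:
        for name in ("n_addictive", "n_targets", "n_categories", "corpus_total"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_nonaddictive_pool < 0 or self.n_gene_sets < 0:
            raise ConfigError("pool and gene-set counts must be non-negative")
        if self.drug_degree_gamma <= 1:
            raise ConfigError("power-law exponent must exceed 1")
        for name in ("p_zero_target", "category_cohesion"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.n_targets < self.n_categories:
            raise ConfigError("need at least one target per category")
        if self.planted_enriched_sets > self.n_gene_sets:
            raise ConfigError("more planted than total gene sets")
        if self.planted_assoc_drugs > self.n_addictive + self.n_nonaddictive_pool:
            raise ConfigError("more planted association drugs than drugs")

    def stream(self, label: str) -> np.random.Generator:
        """Independent deterministic RNG stream derived from the seed."""
        ids = {"drug_target": 1, "literature": 2, "gene_sets": 3}
        return np.random.default_rng([self.seed, ids[label]])


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    remainder = total - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:remainder]] += 1
    return base


def sample_powerlaw_degrees(
    rng: np.random.Generator, size: int, gamma: float, kmax: int = MAX_DRUG_DEGREE
) -> np.ndarray:
    """Discrete truncated power law on {1..kmax}: P(k) proportional to k^-gamma."""
    ks = np.arange(1, kmax + 1)
    probs = ks.astype(float) ** -gamma
    probs /= probs.sum()
    return rng.choice(ks, size=size, p=probs)


def _category_names(n_categories: int) -> list[str]:
    if n_categories <= len(NIDA_CATEGORIES):
        return list(NIDA_CATEGORIES[:n_categories])
    names = list(NIDA_CATEGORIES)
    names += [f"synthetic category {i}" for i in range(len(NIDA_CATEGORIES), n_categories)]
    return names


def simulate_drug_target_data(
    config: SimulationConfig,
) -> tuple[list[DrugRecord], list[DrugRecord], list[TargetRecord]]:
    """Generate addictive drugs, a non-addictive pool, and their targets.

    Addictive targets are named ``G0001..``; the private (pool-only) gene
    pool, twice the addictive universe, is named ``P0001..``. ATC letters
    are attached so the classification screen has realistic input: most
    addictive drugs are nervous-system (N) class, the pool is mixed.
    """
    config.validate()
    rng = config.stream("drug_target")
    targets = [f"G{i + 1:04d}" for i in range(config.n_targets)]
    private = [f"P{i + 1:04d}" for i in range(2 * config.n_targets)]

    if config.n_categories == 6:
        weights = np.array(CATEGORY_WEIGHTS, dtype=float)
    else:
        weights = np.ones(config.n_categories)
    cat_sizes = _largest_remainder(weights, config.n_addictive)
    cat_names = _category_names(config.n_categories)
    block_sizes = _largest_remainder(np.ones(config.n_categories), config.n_targets)
    block_edges = np.concatenate([[0], np.cumsum(block_sizes)])
    blocks = [targets[block_edges[i]: block_edges[i + 1]] for i in range(config.n_categories)]

    addictive: list[DrugRecord] = []
    idx = 0
    for cat_idx, size in enumerate(cat_sizes):
        for _ in range(size):
            idx += 1
            drug_id = f"SYN{idx:05d}"
            if rng.random() < config.p_zero_target:
                chosen: set[str] = set()
            else:
                degree = int(
                    sample_powerlaw_degrees(rng, 1, config.drug_degree_gamma)[0]
                )
                block = blocks[cat_idx]
                n_own = min(int(rng.binomial(degree, config.category_cohesion)), len(block))
                chosen = set(rng.choice(block, size=n_own, replace=False))
                outside = [t for t in targets if t not in chosen]
                n_rest = min(degree - n_own, len(outside))
                if n_rest > 0:
                    chosen |= set(rng.choice(outside, size=n_rest, replace=False))
            atc = set()
            if rng.random() < 0.9:  # coded fraction
                letter = "N" if rng.random() < 0.85 else rng.choice(list(ATC_LETTERS))
                atc = {f"{letter}{rng.integers(1, 8):02d}AA{rng.integers(1, 99):02d}"}
            addictive.append(
                DrugRecord(
                    drug_id=drug_id,
                    name=f"synthetic drug {idx}",
                    groups={"approved"},
                    nida_category=cat_names[cat_idx],
                    atc_codes=atc,
                    targets=chosen,
                )
            )

    combined = targets + private
    nonaddictive: list[DrugRecord] = []
    degrees = sample_powerlaw_degrees(
        rng, config.n_nonaddictive_pool, config.drug_degree_gamma
    )
    for j in range(config.n_nonaddictive_pool):
        idx += 1
        chosen = set(rng.choice(combined, size=int(degrees[j]), replace=False))
        atc = set()
        if rng.random() < 0.7:
            letter = "N" if rng.random() < 0.5 else rng.choice(list(ATC_LETTERS))
            atc = {f"{letter}{rng.integers(1, 8):02d}AA{rng.integers(1, 99):02d}"}
        nonaddictive.append(
            DrugRecord(
                drug_id=f"SYN{idx:05d}",
                name=f"synthetic drug {idx}",
                groups={"approved"},
                nida_category=NIDA_NONE,
                atc_codes=atc,
                targets=chosen,
            )
        )

    used = sorted(set(targets) | {g for d in nonaddictive for g in d.targets})
    target_records = [TargetRecord(gene_symbol=g) for g in used]
    return addictive, nonaddictive, target_records


def simulate_literature_counts(
    drugs: list[DrugRecord], config: SimulationConfig
) -> tuple[LiteratureCountTable, set[str]]:
    """PubMed-style count triples with a planted associated subset.

    Null drugs: ``n_both`` is hypergeometric given the margins, i.e.
    drug and keyword mentions are independent across abstracts. Planted
    drugs: ``n_both`` is Poisson around ``ratio x expected`` (clipped to
    the margins), so a ratio of 1 reduces to the null.
    """
    config.validate()
    rng = config.stream("literature")
    n_keyword = config.keyword_abstracts
    n_planted = min(config.planted_assoc_drugs, len(drugs))
    planted_ids = set(
        rng.choice([d.drug_id for d in drugs], size=n_planted, replace=False)
    )
    rows = []
    for drug in drugs:
        n_drug = int(np.clip(rng.lognormal(np.log(500), 1.0), 20, 1_000_000))
        expected = n_drug * n_keyword / config.corpus_total
        if drug.drug_id in planted_ids:
            lam = config.planted_assoc_ratio * expected
        else:
            lam = None
        if lam is None:
            n_both = int(rng.hypergeometric(n_keyword, config.corpus_total - n_keyword, n_drug))
        else:
            n_both = int(min(rng.poisson(lam), n_drug, n_keyword))
        rows.append(
            LiteratureCountRow(
                drug_id=drug.drug_id, n_drug=n_drug, n_keyword=n_keyword, n_both=n_both
            )
        )
    table = LiteratureCountTable(corpus_total=config.corpus_total, rows=rows)
    table.validate()
    return table, planted_ids


def simulate_gene_sets(
    target_genes: list[str], config: SimulationConfig
) -> tuple[GeneSetCollection, set[str]]:
    """Gene sets over a universe containing the target genes.

    Planted sets have 20 members of which 60% come from the target list
    (far above hypergeometric expectation); null sets are uniform draws
    from the universe.
    """
    config.validate()
    rng = config.stream("gene_sets")
    targets = sorted(set(target_genes))
    n_filler = max(config.universe_size - len(targets), 0)
    universe = targets + [f"U{i + 1:05d}" for i in range(n_filler)]
    collection = GeneSetCollection()
    planted_ids = set()
    for i in range(config.n_gene_sets):
        set_id = f"SET{i + 1:04d}"
        if i < config.planted_enriched_sets:
            size = 20
            n_from_targets = min(12, len(targets))
            members = set(rng.choice(targets, size=n_from_targets, replace=False))
            rest = [g for g in universe if g not in members]
            members |= set(rng.choice(rest, size=size - n_from_targets, replace=False))
            planted_ids.add(set_id)
            desc = "planted enriched set"
        else:
            size = int(rng.integers(10, 101))
            members = set(rng.choice(universe, size=size, replace=False))
            desc = "null set"
        collection.add(set_id, members, desc)
    return collection, planted_ids
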