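"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates, at desk scale, the structure of a comparative
study of root-associated fungi: a species tree, lifestyle evolution along
it, gene-family copy numbers evolving by a birth-death chain with
lifestyle-dependent gain rates for a planted discriminative set, an
amplicon survey with planted root-enriched taxa, plate phenotype and
qPCR records coupled to a planted "aggressiveness" family, and per-strain
differential-expression tables sharing a planted core of in-planta
over-expressed orthogroups.

Everything is deterministic under (config, seed): per-stage random
streams are spawned from one seed sequence.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    LIFESTYLES, AbundanceSurvey, Bundle, DETable, GeneFamilyMatrix,
    LifestyleMap, Phylogeny, PlatePhenotypeSet, QpcrRecords,
)

_CAZYME_SUBFAMILIES = ["GH10", "AA9", "PL1_7", "GH5_5", "PL3_2", "CE5",
                       "GH28", "AA2", "GH7", "PL4_1"]

_BRANCH_STEP = 0.05  # max step length for the copy-number chain


@dataclass
class SimulationConfig:
    """All knobs of the generator, with study-condition defaults."""

    # tree / lifestyles
    n_tips: int = 60
    n_families: int = 2000
    lifestyles: tuple[str, ...] = LIFESTYLES
    switch_rate: float = 0.3          # lifestyle switches per unit branch

    # gene-family evolution: fast subcritical turnover, so copy numbers
    # equilibrate within a few branch lengths and track the current
    # lifestyle rather than deep history (convergent repertoire evolution)
    root_geom_p: float = 0.5          # P(k) = p(1-p)^k on {0,1,...}, mean 1
    gain_rate: float = 1.2            # per family and per copy, per unit branch
    loss_rate: float = 4.8            # per copy, per unit branch
    n_planted: int = 10               # discriminative families
    planted_effect: float = 4.0       # gain-rate multiplier in target lifestyles
    target_group: tuple[str, ...] = ("MyM", "EF")
    # every lifestyle additionally carries its own signature families
    # (gain rate raised on branches evolving in that lifestyle), so gene
    # content is informative about all lifestyles, not only the target
    # group — the premise of lifestyle classification from repertoires
    signature_size: int = 10          # families per lifestyle
    signature_effect: float = 4.0     # gain-rate multiplier
    frac_cazyme: float = 0.10
    frac_secreted: float = 0.30
    planted_frac_cazyme: float = 0.60  # flag enrichment among planted families
    planted_frac_secreted: float = 0.80

    # amplicon survey
    n_taxa: int = 100
    n_root: int = 30
    n_soil: int = 30
    n_enriched: int = 10
    enrichment_fold: float = 8.0
    base_concentration: float = 0.5   # Dirichlet parameter per taxon
    depth_log_mean: float = math.log(8000.0)
    depth_log_sd: float = 1.0         # lognormal depths; some fall below 1000

    # plate phenotypes / qPCR
    n_strains: int = 40
    n_plates: int = 15                # per strain and Pi level
    seeds_per_plate: int = 7
    mock_sfw_mean: float = 50.0       # mg
    sfw_sd: float = 10.0              # mg
    germination_base: float = 0.9
    germination_slope: float = 0.3
    coupling: float = 0.3             # c: strength of aggressiveness -> effect
    effect_noise: float = 0.05
    cq_base: float = 22.0
    cq_slope: float = 6.0             # lower Cq(ITS1) for more aggressive strains
    cq_noise: float = 0.3
    cq_ubq10_mean: float = 20.0
    n_qpcr_samples: int = 4           # per strain

    # expression
    n_expr_strains: int = 6
    core_size: int = 26
    n_de_genes: int = 100             # strain-specific significant genes
    n_null_genes: int = 200
    de_alpha: float = 0.05

    def validate(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.n_planted > self.n_families:
            raise ValueError("n_planted exceeds n_families")
        n_other = len(self.lifestyles) - len(set(self.target_group))
        if self.n_planted + self.signature_size * n_other > self.n_families:
            raise ValueError(
                "planted + signature families exceed n_families")
        for name in ("switch_rate", "gain_rate", "loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.enrichment_fold <= 0:
            raise ValueError("enrichment_fold must be > 0")
        if self.mock_sfw_mean <= 0:
            raise ValueError("mock_sfw_mean must be > 0")
        if not 0 < self.root_geom_p <= 1:
            raise ValueError("root_geom_p must be in (0, 1]")
        if self.core_size > self.n_families:
            raise ValueError("core_size exceeds n_families")
        if not set(self.target_group) <= set(self.lifestyles):
            raise ValueError("target_group outside lifestyle vocabulary")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["lifestyles"] = list(d["lifestyles"])
        d["target_group"] = list(d["target_group"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted truths the downstream stages are asked to recover."""

    ancestral_lifestyles: pd.Series        # internal node -> lifestyle
    ancestral_counts: pd.DataFrame         # node x family true copy numbers
    planted_families: list[str]
    aggressiveness_family: str | None
    enriched_taxa: list[str]
    strain_effects: pd.Series              # strain -> delta (signed)
    core_orthogroups: list[str]


def _stage_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def simulate_tree(config: SimulationConfig, seed: int) -> Phylogeny:
    """Pure-birth (Yule) tree, branch lengths rescaled to mean 1."""
    config.validate()
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=config.n_tips,
        rng=random.Random(seed))
    tree.seed_node.edge.length = None
    # deterministic tip names G01.. in ladderized preorder
    tree.ladderize()
    width = len(str(config.n_tips))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"G{i:0{width}d}"
    edges = [n.edge for n in tree.preorder_node_iter()
             if n.parent_node is not None]
    for e in edges:  # birth-death sampling can leave exactly-zero edges
        e.length = max(e.length or 0.0, 1e-6)
    mean = sum(e.length for e in edges) / len(edges)
    for e in edges:
        e.length /= mean
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# Lifestyles
# ---------------------------------------------------------------------------

def simulate_lifestyles(tree: Phylogeny, config: SimulationConfig, seed: int
                        ) -> tuple[LifestyleMap, pd.Series]:
    """Markov lifestyle switching along branches.

    The root lifestyle is uniform; along a branch of length t the state
    switches with probability 1 - exp(-s*t) to a uniformly chosen other
    state.  Returns the tip map and the internal-node truth.
    """
    states = list(config.lifestyles)
    if not states:
        raise ValueError("empty lifestyle set")
    rng = np.random.default_rng(seed)
    s = config.switch_rate
    assignment: dict[int, str] = {}
    tip_states, internal_states = {}, {}
    for node in tree.preorder_nodes():
        if node.parent_node is None:
            state = states[rng.integers(len(states))]
        else:
            state = assignment[id(node.parent_node)]
            t = node.edge.length or 0.0
            if len(states) > 1 and rng.random() < 1.0 - math.exp(-s * t):
                others = [x for x in states if x != state]
                state = others[rng.integers(len(others))]
        assignment[id(node)] = state
        if node.is_leaf():
            tip_states[node.taxon.label] = state
        else:
            internal_states[node.label] = state
    tips = pd.Series(tip_states, name="lifestyle").loc[tree.tip_names]
    internal = pd.Series(internal_states, name="lifestyle").loc[
        tree.internal_node_names]
    lsm = LifestyleMap(tips, tips.isin(config.target_group))
    return lsm, internal


# ---------------------------------------------------------------------------
# Gene families
# ---------------------------------------------------------------------------

def _evolve_branch(counts: np.ndarray, length: float, gain: np.ndarray,
                   loss: float, rng: np.random.Generator) -> np.ndarray:
    """Birth-death chain for all families along one branch.

    Per step of length dt: gains ~ Poisson(gain*dt*(1+n)) (innovation plus
    per-copy duplication), losses ~ Binomial(n, loss*dt).
    """
    n = counts.copy()
    n_steps = max(1, math.ceil(length / _BRANCH_STEP))
    dt = length / n_steps
    p_loss = min(1.0, loss * dt)
    for _ in range(n_steps):
        gains = rng.poisson(gain * dt * (1 + n))
        losses = rng.binomial(n, p_loss)
        n = n + gains - losses
    return n


def simulate_gene_matrix(tree: Phylogeny, lifestyles: LifestyleMap,
                         internal_lifestyles: pd.Series,
                         config: SimulationConfig, seed: int
                         ) -> tuple[GeneFamilyMatrix, pd.DataFrame, list[str], str | None]:
    """Evolve copy numbers down the tree with planted lifestyle effects.

    The ``n_planted`` families get their gain rate multiplied by
    ``planted_effect`` on branches whose child node lifestyle is in the
    target group (>1 plants enrichment, <1 depletion).  Returns the tip
    matrix, the true per-node counts, the planted family ids and the
    designated aggressiveness family (a planted pectate-lyase analogue).
    """
    rng = np.random.default_rng(seed)
    fam_width = len(str(config.n_families))
    family_ids = [f"OG{i:0{fam_width}d}" for i in range(1, config.n_families + 1)]
    target = set(config.target_group)
    # the target group's genomic signature IS the planted discriminative
    # set; every other lifestyle gets its own signature families so that
    # gene content is informative about all lifestyles
    others = [ls for ls in config.lifestyles if ls not in target]
    n_sig = config.signature_size * len(others)
    drawn = rng.choice(config.n_families, size=config.n_planted + n_sig,
                       replace=False)
    planted_idx = drawn[:config.n_planted]
    planted = [family_ids[i] for i in sorted(planted_idx)]
    is_planted = np.zeros(config.n_families, dtype=bool)
    is_planted[planted_idx] = True
    signature_idx = {
        ls: drawn[config.n_planted + i * config.signature_size:
                  config.n_planted + (i + 1) * config.signature_size]
        for i, ls in enumerate(others)
    }
    for ls in target:
        signature_idx[ls] = np.array([], dtype=int)

    node_state = {n: s for n, s in internal_lifestyles.items()}
    node_state.update(lifestyles.labels.to_dict())

    root_counts = rng.geometric(config.root_geom_p, config.n_families) - 1
    counts_by_node: dict[str, np.ndarray] = {}
    store: dict[int, np.ndarray] = {}
    for node in tree.preorder_nodes():
        name = Phylogeny.node_name(node)
        if node.parent_node is None:
            c = root_counts
        else:
            parent = store[id(node.parent_node)]
            gain = np.full(config.n_families, config.gain_rate)
            state = node_state[name]
            if state in target:
                gain[is_planted] *= config.planted_effect
            gain[signature_idx[state]] *= config.signature_effect
            c = _evolve_branch(parent, node.edge.length or 0.0, gain,
                               config.loss_rate, rng)
        store[id(node)] = c
        counts_by_node[name] = c

    tips = pd.DataFrame({g: counts_by_node[g] for g in tree.tip_names},
                        index=family_ids).T
    true_counts = pd.DataFrame(
        {n: counts_by_node[n] for n in tree.node_names}, index=family_ids).T

    # annotations: planted families carry enriched CAZyme/secreted flags
    p_caz = np.where(is_planted, config.planted_frac_cazyme, config.frac_cazyme)
    is_caz = rng.random(config.n_families) < p_caz
    other_cat = rng.choice(["protease", "lipase", "SSP", "other"],
                           size=config.n_families, p=[0.1, 0.05, 0.15, 0.7])
    category = np.where(is_caz, "CAZyme", other_cat)
    p_sec = np.where(is_planted, config.planted_frac_secreted,
                     config.frac_secreted)
    secreted = rng.random(config.n_families) < p_sec
    sub = np.where(
        is_caz, rng.choice(_CAZYME_SUBFAMILIES, size=config.n_families), "")
    aggressiveness = None
    if config.n_planted:
        ai = sorted(planted_idx)[0]
        aggressiveness = family_ids[ai]
        category[ai] = "CAZyme"
        sub[ai] = "PL1_7"
        secreted[ai] = True
    pcwde = is_caz & (rng.random(config.n_families) < 0.5)
    fcwde = is_caz & ~pcwde & (rng.random(config.n_families) < 0.5)
    ann = pd.DataFrame({
        "category": category, "subfamily": sub, "secreted": secreted,
        "pcwde": pcwde, "fcwde": fcwde,
    }, index=pd.Index(family_ids, name="family_id"))
    ann = ann[ann["category"] != "other"]  # unannotated families default
    gfm = GeneFamilyMatrix(tips, ann)
    return gfm, true_counts, planted, aggressiveness


# ---------------------------------------------------------------------------
# Amplicon survey
# ---------------------------------------------------------------------------

def simulate_survey(config: SimulationConfig, seed: int
                    ) -> tuple[AbundanceSurvey, list[str]]:
    """Dirichlet-multinomial survey with planted root-enriched taxa."""
    if config.n_root < 2 or config.n_soil < 2:
        raise ValueError("need at least 2 samples per compartment")
    config.validate()
    rng = np.random.default_rng(seed)
    width = len(str(config.n_taxa))
    taxa = [f"T{i:0{width}d}" for i in range(1, config.n_taxa + 1)]
    enriched_idx = rng.choice(config.n_taxa, size=config.n_enriched,
                              replace=False)
    enriched = [taxa[i] for i in sorted(enriched_idx)]
    base = np.full(config.n_taxa, config.base_concentration)
    root_conc = base.copy()
    root_conc[enriched_idx] *= config.enrichment_fold

    rows, meta = [], []
    sids = []
    for i in range(config.n_root):
        sids.append(f"R{i + 1:03d}")
        meta.append(("root", f"site{i % 3 + 1}"))
    for i in range(config.n_soil):
        sids.append(f"S{i + 1:03d}")
        meta.append(("soil", f"site{i % 3 + 1}"))
    for sid, (comp, _site) in zip(sids, meta):
        conc = root_conc if comp == "root" else base
        props = rng.dirichlet(conc)
        depth = max(50, int(rng.lognormal(config.depth_log_mean,
                                          config.depth_log_sd)))
        rows.append(rng.multinomial(depth, props))
    counts = pd.DataFrame(rows, index=pd.Index(sids, name="sample_id"),
                          columns=taxa)
    metadata = pd.DataFrame(meta, index=pd.Index(sids, name="sample_id"),
                            columns=["compartment", "site"])
    return AbundanceSurvey(counts, metadata), enriched


# ---------------------------------------------------------------------------
# Plate phenotypes and qPCR
# ---------------------------------------------------------------------------

def simulate_phenotypes(config: SimulationConfig, matrix: GeneFamilyMatrix,
                        aggressiveness_family: str, seed: int
                        ) -> tuple[PlatePhenotypeSet, QpcrRecords, pd.Series]:
    """Plate-level plant performance coupled to the aggressiveness family.

    Strain effect delta_i = -c * z_i + noise where z_i is the
    median-centered, sd-scaled copy number of the aggressiveness family:
    strains with more copies depress plant performance.  Median centering
    keeps the typical strain near neutral (the copy-number distribution
    is right-skewed), matching recolonization panels where most isolates
    leave the host unaffected.  Colonization (qPCR) increases with
    aggressiveness, so Cq(ITS1) decreases.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    strains = matrix.genome_ids[:min(config.n_strains, len(matrix.genome_ids))]
    agg = matrix.counts[aggressiveness_family].loc[strains].to_numpy(float)
    sd = agg.std()
    z = (agg - np.median(agg)) / sd if sd > 0 else np.zeros_like(agg)
    delta = -config.coupling * z + rng.normal(0, config.effect_noise, len(strains))
    effects = pd.Series(delta, index=pd.Index(strains, name="strain"),
                        name="delta")

    plate_rows = []
    plate_ids = []
    k = 0
    for strain, d in [("mock", 0.0)] + list(zip(strains, delta)):
        for pi in ("low", "high"):
            for _ in range(config.n_plates):
                k += 1
                g = float(np.clip(config.germination_base
                                  + config.germination_slope * d, 0.05, 1.0))
                grown = int(rng.binomial(config.seeds_per_plate, g))
                mu = config.mock_sfw_mean * (1.0 + d)
                sfw = rng.normal(mu, config.sfw_sd, grown)
                sfw = np.maximum(sfw, 1e-3)  # SFW is a positive weight
                plate_ids.append(f"P{k:05d}")
                plate_rows.append({
                    "strain": strain, "pi_level": pi,
                    "seeds_sown": config.seeds_per_plate,
                    "plants_grown": grown,
                    "sfw_mg": [round(float(x), 6) for x in sfw],
                })
    plates = PlatePhenotypeSet(pd.DataFrame(
        plate_rows, index=pd.Index(plate_ids, name="plate_id")))

    q_rows, q_ids = [], []
    for i, (strain, d) in enumerate(zip(strains, delta)):
        for j in range(config.n_qpcr_samples):
            q_ids.append(f"Q{i + 1:03d}_{j + 1}")
            q_rows.append({
                "strain": strain,
                "cq_its1": float(config.cq_base + config.cq_slope * d
                                 + rng.normal(0, config.cq_noise)),
                "cq_ubq10": float(rng.normal(config.cq_ubq10_mean,
                                             config.cq_noise)),
            })
    qpcr = QpcrRecords(pd.DataFrame(q_rows, index=pd.Index(q_ids, name="sample_id")))
    return plates, qpcr, effects


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig, family_ids: list[str],
                        seed: int) -> tuple[list[DETable], list[str]]:
    """Per-strain DE tables sharing a planted core of induced orthogroups."""
    if config.n_expr_strains < 2:
        raise ValueError("need at least 2 strains")
    if config.core_size > len(family_ids):
        raise ValueError("core_size exceeds number of families")
    rng = np.random.default_rng(seed)
    fams = np.array(family_ids)
    core_idx = rng.choice(len(fams), size=config.core_size, replace=False)
    core = [str(f) for f in fams[np.sort(core_idx)]]
    non_core = np.setdiff1d(np.arange(len(fams)), core_idx)

    tables = []
    for s in range(1, config.n_expr_strains + 1):
        strain = f"Strain{s}"
        genes, lfc, padj, ogs = [], [], [], []
        gid = 0
        for og in core:
            for _ in range(int(rng.integers(1, 4))):
                gid += 1
                genes.append(f"{strain}_g{gid:05d}")
                lfc.append(float(np.abs(rng.normal(2.5, 0.5)) + 0.1))
                padj.append(float(rng.uniform(1e-6, config.de_alpha * 0.99)))
                ogs.append(og)
        de_idx = rng.choice(non_core, size=min(config.n_de_genes, len(non_core)),
                            replace=False)
        for i in de_idx:
            gid += 1
            genes.append(f"{strain}_g{gid:05d}")
            lfc.append(float(rng.normal(0, 2)))
            padj.append(float(rng.uniform(1e-6, config.de_alpha * 0.99)))
            ogs.append(str(fams[i]))
        null_idx = rng.choice(len(fams), size=config.n_null_genes, replace=True)
        for i in null_idx:
            gid += 1
            genes.append(f"{strain}_g{gid:05d}")
            lfc.append(float(rng.normal(0, 1)))
            padj.append(float(rng.uniform(config.de_alpha, 1.0)))
            ogs.append(str(fams[i]))
        df = pd.DataFrame({"log2fc": lfc, "padj": padj},
                          index=pd.Index(genes, name="gene_id"))
        gene_map = pd.Series(ogs, index=pd.Index(genes, name="gene_id"),
                             name="orthogroup")
        tables.append(DETable(strain, df, gene_map))
    return tables, core


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig, seed: int
                    ) -> tuple[Bundle, GroundTruth]:
    """Generate every pipeline input plus the planted ground truth."""
    config.validate()
    seeds = np.random.SeedSequence(seed).generate_state(6) % (2 ** 31)
    tree = simulate_tree(config, int(seeds[0]))
    lifestyles, internal_ls = simulate_lifestyles(tree, config, int(seeds[1]))
    matrix, true_counts, planted, agg = simulate_gene_matrix(
        tree, lifestyles, internal_ls, config, int(seeds[2]))
    survey, enriched = simulate_survey(config, int(seeds[3]))
    plates, qpcr, effects = simulate_phenotypes(config, matrix, agg,
                                                int(seeds[4]))
    de_tables, core = simulate_expression(config, matrix.family_ids,
                                          int(seeds[5]))
    bundle = Bundle(tree, matrix, lifestyles, survey, plates, qpcr, de_tables)
    truth = GroundTruth(
        ancestral_lifestyles=internal_ls,
        ancestral_counts=true_counts,
        planted_families=planted,
        aggressiveness_family=agg,
        enriched_taxa=enriched,
        strain_effects=effects,
        core_orthogroups=core,
    )
    return bundle, truth
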