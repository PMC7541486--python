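"""Synthetic case/control snRNA-seq cohorts with planted ground truth.

The generator emulates the structure of a human-cortex case/control cohort:
~10 control and ~9 case samples, a 4-level subtype hierarchy split into
principal neurons and GABAergic interneurons, negative-binomial counts with
per-subtype expression programs, condition effects planted in chosen subtypes,
latent-factor co-expression modules, and case/control composition shifts.

Counts are gamma-Poisson (negative binomial): each cell's expected expression
is library-size share × subtype program × condition effect × module factor,
overdispersed by a shared dispersion. One global seed drives independent
per-sample substreams, so enlarging one sample leaves the others bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import AnnotatedCounts, ConfigurationError

_PRINCIPAL_FAMILIES = ["L2_Cux2", "L3_Cux2", "L4_Rorb", "L5-6_Fezf2", "L5-6_Themis"]
_INTERNEURON_FAMILIES = ["Pvalb", "Sst", "Vip", "Id2"]
_LEAF_TAGS = [
    "Lamp5", "Frem3", "Prss12", "Met", "Mme", "Tle4", "Lrrk1", "Ntng2", "Sema3a",
    "Sulf1", "Nos1", "Tac1", "Tac3", "Cbln1", "Nrg1", "Abi3bp", "Crh", "Sstr1",
    "Nmbr", "Nckap5", "Abo", "Sema3e", "Th", "Calb1", "Grik3", "Htr2c",
]


@dataclass
class ModuleSpec:
    """A planted co-expression module.

    loading is the log-normal sigma of the per-cell latent factor that
    multiplies member-gene means; condition_coupling shifts the latent factor's
    log-mean in case cells, coupling module expression to condition. scope
    restricts the factor to the named level4 subtypes (None = all cells).
    """

    size: int
    loading: float = 0.5
    scope: Sequence[str] | None = None
    condition_coupling: float = 0.0


@dataclass
class CohortConfig:
    """Study-condition parameters for one synthetic cohort."""

    n_control_samples: int = 10
    n_case_samples: int = 9
    n_subtypes: int = 30
    cells_per_sample_per_subtype: float = 40.0
    n_genes: int = 2000
    nb_dispersion: float = 0.15
    library_size: float = 2500.0
    library_sigma: float = 0.25
    program_sigma: float = 0.5
    # list of (subtype name or index, n_de_genes, |log2 fold change|)
    affected_subtypes: list[tuple] = field(default_factory=list)
    planted_modules: list[ModuleSpec] = field(default_factory=list)
    # list of (subtype name or index, case/control proportion ratio)
    composition_shifts: list[tuple] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_control_samples", "n_case_samples", "n_subtypes", "n_genes",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.cells_per_sample_per_subtype <= 0:
            raise ConfigurationError("cells_per_sample_per_subtype must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.library_size <= 0:
            raise ConfigurationError("library_size must be positive")
        names = set(subtype_names(self.n_subtypes)["level4"])
        for st, n_de, lfc in self.affected_subtypes:
            if self._resolve(st) not in names:
                raise ConfigurationError(f"affected_subtypes: unknown subtype {st!r}")
            if n_de < 1 or n_de > self.n_genes:
                raise ConfigurationError("affected_subtypes: n_de_genes out of range")
            if lfc <= 0:
                raise ConfigurationError("affected_subtypes: log2fc must be positive")
        for st, ratio in self.composition_shifts:
            if self._resolve(st) not in names:
                raise ConfigurationError(f"composition_shifts: unknown subtype {st!r}")
            if ratio <= 0:
                raise ConfigurationError("composition_shifts: ratio must be positive")
        for m in self.planted_modules:
            if m.size < 2 or m.size > self.n_genes:
                raise ConfigurationError("planted_modules: size out of range")
            if m.loading <= 0:
                raise ConfigurationError("planted_modules: loading must be positive")
            if m.scope is not None:
                unknown = set(m.scope) - names
                if unknown:
                    raise ConfigurationError(
                        f"planted_modules: unknown scope subtypes {sorted(unknown)}"
                    )

    def _resolve(self, subtype) -> str:
        if isinstance(subtype, (int, np.integer)):
            return subtype_names(self.n_subtypes)["level4"][int(subtype)]
        return str(subtype)


@dataclass
class TruthRecord:
    """Planted ground truth; a pure function of (CohortConfig, seed)."""

    config: CohortConfig
    subtype_table: pd.DataFrame  # level1..level4, class per subtype
    de_truth: pd.DataFrame  # columns: subtype, gene, log2fc
    module_members: dict[str, list[str]]
    base_proportions: pd.Series  # control per-subtype proportions
    case_proportions: pd.Series
    expected_mean: pd.DataFrame  # subtype × gene expected control counts/cell

    @property
    def affected_subtypes(self) -> list[str]:
        return sorted(self.de_truth["subtype"].unique())


def subtype_names(n_subtypes: int) -> pd.DataFrame:
    """Deterministic 4-level hierarchy template split into the two classes.

    Roughly 40% principal / 60% interneuron leaves, echoing cortical
    annotation schemes (L2_Cux2_*, Pvalb_*); the names carry no biology.
    """
    n_principal = max(1, int(round(n_subtypes * 0.4)))
    n_inter = n_subtypes - n_principal
    rows = []
    for cls, families, count in (
        ("principal", _PRINCIPAL_FAMILIES, n_principal),
        ("interneuron", _INTERNEURON_FAMILIES, n_inter),
    ):
        for i in range(count):
            fam = families[i % len(families)]
            tag = _LEAF_TAGS[i % len(_LEAF_TAGS)]
            sub = f"{fam}_{tag}" if i < len(_LEAF_TAGS) else f"{fam}_{tag}{i}"
            rows.append(
                {
                    "level1": "Principal" if cls == "principal" else "Interneuron",
                    "level2": fam,
                    "level3": f"{fam}_{tag[:3]}",
                    "level4": sub,
                    "class": cls,
                }
            )
    table = pd.DataFrame(rows)
    if table["level4"].duplicated().any():  # disambiguate large panels
        table["level4"] = [
            f"{s}_{i}" if d else s
            for i, (s, d) in enumerate(zip(table["level4"], table["level4"].duplicated()))
        ]
    return table


def _structure_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), 0]))


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), 1, sample_index]))


def generate_cohort(config: CohortConfig) -> tuple[AnnotatedCounts, TruthRecord]:
    """Draw an annotated cohort and its ground-truth record."""
    config.validate()
    table = subtype_names(config.n_subtypes)
    subtypes = table["level4"].tolist()
    genes = pd.Index([f"G{j:05d}" for j in range(config.n_genes)], name="gene_id")
    rng = _structure_rng(config.seed)

    # base expression and per-subtype programs (relative expression shares)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    program = np.exp(
        config.program_sigma * rng.standard_normal((config.n_subtypes, config.n_genes))
    )
    rel = base[None, :] * program  # subtype × gene, unnormalized

    # condition effects
    lfc = np.zeros((config.n_subtypes, config.n_genes))
    de_rows = []
    for st, n_de, mag in config.affected_subtypes:
        name = config._resolve(st)
        t = subtypes.index(name)
        de_genes = rng.choice(config.n_genes, size=int(n_de), replace=False)
        signs = rng.choice([-1.0, 1.0], size=int(n_de))
        lfc[t, de_genes] = signs * mag
        for g, s in zip(de_genes, signs):
            de_rows.append({"subtype": name, "gene": genes[g], "log2fc": s * mag})
    de_truth = pd.DataFrame(de_rows, columns=["subtype", "gene", "log2fc"])

    # planted modules: disjoint member draws from non-DE genes where possible
    taken: set[int] = set()
    module_members: dict[str, list[str]] = {}
    module_idx: list[np.ndarray] = []
    for mi, m in enumerate(config.planted_modules):
        pool = np.array([g for g in range(config.n_genes) if g not in taken])
        if len(pool) < m.size:
            raise ConfigurationError("planted_modules: sizes exceed gene count")
        members = rng.choice(pool, size=m.size, replace=False)
        taken.update(members.tolist())
        module_members[f"module_{mi}"] = [genes[g] for g in sorted(members)]
        module_idx.append(np.sort(members))

    # composition
    base_props = pd.Series(
        rng.dirichlet(np.full(config.n_subtypes, 5.0)), index=subtypes
    )
    case_props = base_props.copy()
    for st, ratio in config.composition_shifts:
        case_props[config._resolve(st)] *= ratio
    case_props /= case_props.sum()

    # expected control counts per cell (library share × program)
    shares = rel / rel.sum(axis=1, keepdims=True)
    expected_mean = pd.DataFrame(
        shares * config.library_size, index=subtypes, columns=genes
    )

    # per-sample generation
    n_total = config.n_control_samples + config.n_case_samples
    sample_ids = [f"C{i + 1}" for i in range(config.n_control_samples)] + [
        f"E{i + 1}" for i in range(config.n_case_samples)
    ]
    conditions = ["control"] * config.n_control_samples + ["case"] * config.n_case_samples
    mean_cells = config.cells_per_sample_per_subtype * config.n_subtypes

    blocks, obs_rows = [], []
    for si in range(n_total):
        srng = _sample_rng(config.seed, si)
        props = (case_props if conditions[si] == "case" else base_props).values
        n_cells = max(config.n_subtypes, srng.poisson(mean_cells))
        cells_per_subtype = srng.multinomial(n_cells, props)
        for t, n_ct in enumerate(cells_per_subtype):
            if n_ct == 0:
                continue
            mu = shares[t].copy()
            if conditions[si] == "case":
                mu = mu * np.exp2(lfc[t])
            mu = np.tile(mu, (n_ct, 1))
            # latent module factors (mean-one log-normal, optionally condition-coupled)
            for m, members in zip(config.planted_modules, module_idx):
                if m.scope is not None and subtypes[t] not in m.scope:
                    continue
                shift = m.condition_coupling if conditions[si] == "case" else 0.0
                u = srng.standard_normal(n_ct) + shift
                f = np.exp(m.loading * u - 0.5 * m.loading**2)
                mu[:, members] *= f[:, None]
            lib = srng.lognormal(
                -0.5 * config.library_sigma**2, config.library_sigma, size=n_ct
            )
            mu *= (config.library_size * lib)[:, None]
            lam = srng.gamma(
                shape=1.0 / config.nb_dispersion, scale=mu * config.nb_dispersion
            )
            blocks.append(sp.csr_matrix(srng.poisson(lam)))
            row = table.iloc[t]
            for _ in range(n_ct):
                obs_rows.append(
                    {
                        "sample_id": sample_ids[si],
                        "condition": conditions[si],
                        "level1": row["level1"],
                        "level2": row["level2"],
                        "level3": row["level3"],
                        "level4": row["level4"],
                        "class": row["class"],
                    }
                )

    X = sp.vstack(blocks, format="csr")
    obs = pd.DataFrame(obs_rows)
    obs.index = pd.Index([f"cell_{i:06d}" for i in range(len(obs))], name="cell_id")
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    truth = TruthRecord(
        config=config,
        subtype_table=table,
        de_truth=de_truth,
        module_members=module_members,
        base_proportions=base_props,
        case_proportions=case_props,
        expected_mean=expected_mean,
    )
    return AnnotatedCounts(adata), truth


# -- gene-set and gene-list fixtures ------------------------------------------


@dataclass
class GeneSetFixtures:
    """A GMT-style collection plus curated/GWAS/autopsy list fixtures."""

    terms: dict[str, list[str]]
    spiked_terms: list[str]
    curated_genes: list[str]
    gwas_genes: list[str]
    autopsy_genes: list[str]


def generate_gene_sets(
    truth: TruthRecord,
    n_terms: int,
    term_size_range: tuple[int, int] = (10, 50),
    enrichment_spike: float = 0.0,
    seed: int = 0,
    n_spiked_terms: int | None = None,
) -> GeneSetFixtures:
    """Random gene-set collection with a designated DE-enriched subset.

    Most terms are uniform random draws from the gene universe; the first
    ``n_spiked_terms`` terms draw each member from the planted DE genes with
    probability ``enrichment_spike`` (uniformly otherwise). Curated and GWAS
    list fixtures over-sample planted DE genes the same way; the autopsy list
    is a plain random draw.
    """
    if n_terms < 1:
        raise ConfigurationError("n_terms must be >= 1")
    lo, hi = term_size_range
    genes = truth.expected_mean.columns.to_numpy()
    if hi > len(genes):
        raise ConfigurationError("term size exceeds gene count")
    de_genes = np.unique(truth.de_truth["gene"].to_numpy()) if len(truth.de_truth) else np.array([], dtype=object)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    if n_spiked_terms is None:
        n_spiked_terms = max(1, n_terms // 10) if enrichment_spike > 0 else 0

    def draw_set(size: int, spike: float) -> list[str]:
        chosen: list[str] = []
        pool = set()
        while len(chosen) < size:
            if spike > 0 and len(de_genes) and rng.random() < spike:
                g = rng.choice(de_genes)
            else:
                g = genes[rng.integers(len(genes))]
            if g not in pool:
                pool.add(g)
                chosen.append(str(g))
        return chosen

    terms, spiked = {}, []
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        spike = enrichment_spike if i < n_spiked_terms else 0.0
        name = f"TERM:{i:04d}"
        terms[name] = draw_set(size, spike)
        if spike > 0:
            spiked.append(name)

    curated = draw_set(min(60, len(genes) // 4), enrichment_spike)
    gwas = draw_set(min(60, len(genes) // 4), enrichment_spike)
    autopsy = draw_set(min(40, len(genes) // 5), 0.0)
    return GeneSetFixtures(terms, spiked, curated, gwas, autopsy)


# -- smFISH fixture -----------------------------------------------------------


def generate_smfish_table(
    n_cells_per_group: dict[str, int],
    group_means: dict[str, float],
    noise: float = 0.3,
    seed: int = 0,
    reference_mean: float = 1000.0,
    n_sections_per_group: int = 3,
) -> pd.DataFrame:
    """Per-cell raw integrated densities for target and reference channels.

    Both channels carry log-normal noise around the group mean (target) and a
    shared reference mean; cells are split over sections within each group.
    """
    if set(n_cells_per_group) != {"control", "case"} or set(group_means) != {
        "control",
        "case",
    }:
        raise ConfigurationError("groups must be exactly {control, case}")
    if min(group_means.values()) <= 0 or reference_mean <= 0:
        raise ConfigurationError("group means must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    rows = []
    for group in ("control", "case"):
        n = int(n_cells_per_group[group])
        sections = rng.integers(n_sections_per_group, size=n)
        target = np.exp(
            np.log(group_means[group]) + noise * rng.standard_normal(n)
        )
        ref = np.exp(np.log(reference_mean) + noise * rng.standard_normal(n))
        for i in range(n):
            rows.append(
                {
                    "cell_id": f"{group}_{i:04d}",
                    "section_id": f"{group}_sec{sections[i]}",
                    "group": group,
                    "target_raw_intensity": target[i],
                    "reference_raw_intensity": ref[i],
                }
            )
    return pd.DataFrame(rows)
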