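"""Synthetic Pinot noir fermentation studies.

Generates complete studies with the statistical structure the downstream
analysis assumes: hierarchically structured (region > site, plus vintage)
Dirichlet-multinomial amplicon communities with single-genus dominance,
inoculant-dominated fermentation transcriptomes whose non-Saccharomyces
activity is only partially coupled to must DNA abundance, spatially
autocorrelated climate covariates, and a truth record sufficient to score
signature recovery without re-reading generator internals.

All randomness derives from a single master seed; each generator draws
from an independent substream (``default_rng([seed, offset])``) so modules
are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CountTable, SampleMetadata, ValidationError
from . import io as tio

logger = logging.getLogger(__name__)

# substream offsets off the master seed
_STREAM_BACTERIA = 11
_STREAM_FUNGI = 13
_STREAM_RNA = 17
_STREAM_ENV = 19

#: Curated lineages for the most abundant must bacteria; taxon 0 is the
#: Tatumella analogue that dominates every must.
BACTERIAL_LINEAGES = [
    "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Erwiniaceae;Tatumella;Tatumella ptyseos",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Acetobacterales;Acetobacteraceae;Gluconobacter;Gluconobacter oxydans",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Acetobacterales;Acetobacteraceae;Gluconobacter;Gluconobacter cerinus",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Erwiniaceae;Pantoea;Pantoea agglomerans",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas;Pseudomonas syringae",
    "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus;Lactobacillus plantarum",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae;Sphingomonas;Sphingomonas melonis",
    "Bacteria;Actinobacteriota;Actinobacteria;Micrococcales;Microbacteriaceae;Curtobacterium;Curtobacterium flaccumfaciens",
]

#: Curated fungal lineages; taxon 0 is the Hanseniaspora uvarum analogue.
FUNGAL_LINEAGES = [
    "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Saccharomycodaceae;Hanseniaspora;Hanseniaspora uvarum",
    "Fungi;Ascomycota;Dothideomycetes;Dothideales;Aureobasidiaceae;Aureobasidium;Aureobasidium pullulans",
    "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Saccharomycodaceae;Hanseniaspora;Hanseniaspora vineae",
    "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Saccharomycetaceae;Saccharomyces;Saccharomyces cerevisiae",
    "Fungi;Ascomycota;Leotiomycetes;Helotiales;Sclerotiniaceae;Botrytis;Botrytis cinerea",
    "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Metschnikowiaceae;Metschnikowia;Metschnikowia pulcherrima",
    "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Pichiaceae;Pichia;Pichia kudriavzevii",
    "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Saccharomycetaceae;Lachancea;Lachancea thermotolerans",
    "Fungi;Ascomycota;Dothideomycetes;Pleosporales;Pleosporaceae;Alternaria;Alternaria alternata",
    "Fungi;Basidiomycota;Microbotryomycetes;Sporidiobolales;Sporidiobolaceae;Rhodotorula;Rhodotorula glutinis",
    "Fungi;Ascomycota;Eurotiomycetes;Eurotiales;Aspergillaceae;Penicillium;Penicillium crustosum",
    "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Saccharomycetaceae;Starmerella;Starmerella bacillaris",
]

ORGANELLE_TAXONOMIES = [
    "Bacteria;Cyanobacteria;Cyanobacteriia;Chloroplast;Chloroplast",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rickettsiales;Mitochondria;Mitochondria",
]

INOCULANT_ORGANISM = "Saccharomyces cerevisiae"
GRAPE_ORGANISM = "Vitis vinifera"
#: RNA-only organisms emulating taxa the amplicon assay misses entirely.
RNA_ONLY_ORGANISMS = ("Rhizopus stolonifer", "Preussia sp BSL10")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study design and effect sizes for a synthetic fermentation study.

    Effect standard deviations are on the (natural) log-abundance scale.
    ``dominance_alpha`` multiplies the expected relative mass of the
    designated dominant taxon (values <= 1 disable dominance).
    ``dna_rna_r2`` is the population coefficient of determination linking
    DNA and RNA relative abundance for transcriptionally active taxa.
    """

    n_regions: int = 8
    sites_per_region: int | tuple[int, ...] = 2
    tanks_per_site: int = 4
    vintages: tuple[str, ...] = ("2016", "2017", "2019")
    rna_vintages: tuple[str, ...] = ("2017", "2019")
    rna_tanks_per_site: int = 2
    n_bacterial_taxa: int = 150
    n_fungal_taxa: int = 100
    n_organelle_asvs: int = 3
    n_genes: int = 200
    n_site_genes: int = 30
    n_grape_genes: int = 20
    genes_per_active_taxon: int = 5
    timepoints_hours: tuple[float, ...] = (2, 6, 16, 64, 112)
    effect_sd_region: float = 0.5
    effect_sd_site: float = 0.5
    effect_sd_vintage: float = 0.25
    gene_effect_sd: float = 1.0
    gene_timepoint_sd: float = 0.5
    dominance_alpha: float = 50.0
    dm_concentration: float = 100.0
    gene_concentration: float = 300.0
    frac_active_taxa: float = 0.1
    dna_rna_r2: float = 0.25
    inoculant_share: float = 0.90
    grape_share: float = 0.03
    rna_only_share: float = 0.002
    library_size_dna: int = 50_000
    library_size_rna: int = 2_000_000
    env_spatial_range: float = 300.0
    dropped_samples: tuple[tuple[str, str, str], ...] = ()
    seed: int = 0

    # -- derived design ---------------------------------------------------
    def sites_by_region(self) -> dict[str, list[str]]:
        if isinstance(self.sites_per_region, int):
            per_region = [self.sites_per_region] * self.n_regions
        else:
            per_region = list(self.sites_per_region)
            if len(per_region) != self.n_regions:
                raise ValidationError(
                    "sites_per_region list length must equal n_regions"
                )
        mapping: dict[str, list[str]] = {}
        k = 0
        for r, n_sites in enumerate(per_region):
            region = f"AVA{r + 1}"
            mapping[region] = []
            for _ in range(n_sites):
                k += 1
                mapping[region].append(f"S{k:02d}")
        return mapping

    @property
    def site_region(self) -> dict[str, str]:
        return {
            s: r for r, sites in self.sites_by_region().items() for s in sites
        }

    @property
    def sites(self) -> list[str]:
        return [s for sites in self.sites_by_region().values() for s in sites]

    def dna_design(self) -> list[tuple[str, str, str]]:
        """(site, vintage, tank) triples for must DNA samples."""
        dropped = set(self.dropped_samples)
        out = []
        for site in self.sites:
            for vintage in self.vintages:
                for t in range(1, self.tanks_per_site + 1):
                    key = (site, vintage, f"T{t}")
                    if key not in dropped:
                        out.append(key)
        return out

    def rna_design(self) -> list[tuple[str, str, str]]:
        """(site, vintage, tank) fermentations followed by 3' tag RNA-seq."""
        if self.rna_tanks_per_site > self.tanks_per_site:
            raise ValidationError("rna_tanks_per_site exceeds tanks_per_site")
        bad = set(self.rna_vintages) - set(self.vintages)
        if bad:
            raise ValidationError(f"rna_vintages not in vintages: {sorted(bad)}")
        return [
            (site, vintage, f"T{t}")
            for site in self.sites
            for vintage in self.rna_vintages
            for t in range(1, self.rna_tanks_per_site + 1)
        ]

    def validate(self) -> None:
        counts = {
            "n_regions": self.n_regions,
            "tanks_per_site": self.tanks_per_site,
            "n_bacterial_taxa": self.n_bacterial_taxa,
            "n_fungal_taxa": self.n_fungal_taxa,
            "library_size_dna": self.library_size_dna,
            "library_size_rna": self.library_size_rna,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValidationError(f"{name} must be >= 1 (got {value})")
        for name in (
            "effect_sd_region",
            "effect_sd_site",
            "effect_sd_vintage",
            "gene_effect_sd",
            "gene_timepoint_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.frac_active_taxa <= 1:
            raise ValidationError("frac_active_taxa must lie in [0, 1]")
        if not 0 <= self.dna_rna_r2 <= 1:
            raise ValidationError("dna_rna_r2 must lie in [0, 1]")
        tps = list(self.timepoints_hours)
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValidationError("timepoints_hours must be strictly increasing")
        if self.n_genes < 0 or self.n_site_genes > max(self.n_genes, 0):
            raise ValidationError("n_site_genes must be <= n_genes")
        if not 0 < self.inoculant_share < 1:
            raise ValidationError("inoculant_share must lie in (0, 1)")
        if self.inoculant_share + self.grape_share >= 1:
            raise ValidationError("inoculant_share + grape_share must be < 1")
        self.sites_by_region()
        self.rna_design()

    # -- presets -----------------------------------------------------------
    @classmethod
    def study_design(cls, seed: int = 0, **overrides) -> "ScenarioConfig":
        """Mirror of the real study layout: 15 sites over 8 regions, 4
        tanks, three vintages of must DNA, two of RNA, one unfermented
        tank in 2019."""
        kw = dict(
            sites_per_region=(2, 2, 2, 2, 2, 2, 2, 1),
            dropped_samples=(("S02", "2019", "T4"),),
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def large_effect(cls, seed: int = 0, **overrides) -> "ScenarioConfig":
        """Strong, vintage-stable site and region effects (the generator's
        high-signal condition used for power and recovery checks)."""
        kw = dict(
            sites_per_region=(2, 2, 2, 2, 2, 2, 2, 1),
            vintages=("2017", "2019"),
            rna_vintages=("2017", "2019"),
            effect_sd_site=1.2,
            effect_sd_region=0.8,
            effect_sd_vintage=0.2,
            gene_effect_sd=1.5,
            dm_concentration=200.0,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def null_effect(cls, seed: int = 0, **overrides) -> "ScenarioConfig":
        """Exchangeable samples: no site/region/vintage effects, no
        dominance, for type-I-error calibration."""
        kw = dict(
            n_regions=2,
            sites_per_region=2,
            tanks_per_site=4,
            vintages=("2017",),
            rna_vintages=("2017",),
            rna_tanks_per_site=2,
            n_bacterial_taxa=30,
            n_fungal_taxa=30,
            n_organelle_asvs=0,
            n_genes=40,
            n_site_genes=0,
            effect_sd_region=0.0,
            effect_sd_site=0.0,
            effect_sd_vintage=0.0,
            gene_effect_sd=0.0,
            dominance_alpha=0.0,
            library_size_dna=5_000,
            library_size_rna=100_000,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vintages"] = list(self.vintages)
        d["rna_vintages"] = list(self.rna_vintages)
        d["timepoints_hours"] = list(self.timepoints_hours)
        d["dropped_samples"] = [list(x) for x in self.dropped_samples]
        if not isinstance(self.sites_per_region, int):
            d["sites_per_region"] = list(self.sites_per_region)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        kw = dict(d)
        for key in ("vintages", "rna_vintages", "timepoints_hours", "sites_per_region"):
            if key in kw and isinstance(kw[key], list):
                kw[key] = tuple(kw[key])
        if "dropped_samples" in kw:
            kw["dropped_samples"] = tuple(tuple(x) for x in kw["dropped_samples"])
        return cls(**kw)


@dataclass
class SyntheticStudy:
    config: ScenarioConfig
    bacterial_counts: CountTable
    fungal_counts: CountTable
    transcript_counts: dict[float, CountTable]
    metadata: SampleMetadata
    truth: dict

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, table in (
            ("bacterial_16S.tsv", self.bacterial_counts),
            ("fungal_ITS.tsv", self.fungal_counts),
        ):
            tio.write_count_table(table, outdir / name)
            written.append(outdir / name)
        for tp, table in self.transcript_counts.items():
            path = outdir / f"transcripts_{tp:g}h.tsv"
            tio.write_count_table(table, path)
            written.append(path)
        tio.write_metadata(self.metadata, outdir / "metadata.tsv")
        tio.write_yaml(self.config.to_dict(), outdir / "scenario.yaml")
        tio.write_json(self.truth, outdir / "truth.json")
        written += [outdir / "metadata.tsv", outdir / "scenario.yaml", outdir / "truth.json"]
        return written


def _softmax(eta: np.ndarray) -> np.ndarray:
    z = eta - eta.max()
    w = np.exp(z)
    return w / w.sum()


def _taxonomy_pool(marker: str, n_taxa: int) -> tuple[list[str], list[str]]:
    """(feature_ids, taxonomy strings) for a marker, padding the curated
    lineages with synthetic species."""
    if marker == "16S":
        pool, prefix, generic = BACTERIAL_LINEAGES, "BASV", "Bacteria;PhylumX;ClassX;OrderX;FamilyX"
    else:
        pool, prefix, generic = FUNGAL_LINEAGES, "FASV", "Fungi;Ascomycota;ClassX;OrderX;FamilyX"
    taxonomy = []
    for i in range(n_taxa):
        if i < len(pool):
            taxonomy.append(pool[i])
        else:
            genus = f"{'Bactogenus' if marker == '16S' else 'Mycogenus'}{i}"
            taxonomy.append(f"{generic};{genus};{genus} incognita{i}")
    ids = [f"{prefix}{i + 1:04d}" for i in range(n_taxa)]
    return ids, taxonomy


def generate_community_counts(cfg: ScenarioConfig, marker: str) -> CountTable:
    """Simulate a marker-gene ASV table over the DNA sampling design.

    Per-taxon baseline log-abundances receive additive region, site and
    vintage effects; each sample's composition is a Dirichlet draw around
    the exponentiated effect vector (concentration ``dm_concentration``,
    giving amplicon-like overdispersion) and counts are multinomial at a
    Poisson depth around ``library_size_dna``.  Taxon 0 (the
    Tatumella/Hanseniaspora analogue) receives the dominance boost.
    """
    cfg.validate()
    if marker not in ("16S", "ITS"):
        raise ValidationError(
            f"invalid marker {marker!r} for community counts; expected 16S or ITS"
        )
    if cfg.library_size_dna < 1:
        raise ValidationError("library_size_dna must be >= 1; all-zero tables rejected")
    rng = np.random.default_rng(
        [cfg.seed, _STREAM_BACTERIA if marker == "16S" else _STREAM_FUNGI]
    )
    n_taxa = cfg.n_bacterial_taxa if marker == "16S" else cfg.n_fungal_taxa
    n_org = cfg.n_organelle_asvs if marker == "16S" else 0
    ids, taxonomy = _taxonomy_pool(marker, n_taxa)
    for i in range(n_org):
        ids.append(f"OASV{i + 1:04d}")
        taxonomy.append(ORGANELLE_TAXONOMIES[i % len(ORGANELLE_TAXONOMIES)])
    n_total = n_taxa + n_org

    base = rng.normal(0.0, 1.5, n_total)
    if cfg.dominance_alpha > 1 and n_total > 1:
        # dominance is relative to the most abundant background taxon, so
        # the designated taxon leads every must regardless of the draw
        base[0] = base[1:].max() + math.log(cfg.dominance_alpha)
    sites = cfg.sites
    regions = list(cfg.sites_by_region())
    site_idx = {s: i for i, s in enumerate(sites)}
    region_idx = {r: i for i, r in enumerate(regions)}
    vint_idx = {v: i for i, v in enumerate(cfg.vintages)}
    site_region = cfg.site_region
    eff_region = rng.normal(0.0, cfg.effect_sd_region, (n_total, len(regions)))
    eff_site = rng.normal(0.0, cfg.effect_sd_site, (n_total, len(sites)))
    eff_vint = rng.normal(0.0, cfg.effect_sd_vintage, (n_total, len(cfg.vintages)))

    design = cfg.dna_design()
    counts = np.zeros((n_total, len(design)), dtype=np.int64)
    sample_ids = []
    for j, (site, vintage, tank) in enumerate(design):
        sample_ids.append(f"{site}-{vintage}-{tank}")
        eta = (
            base
            + eff_region[:, region_idx[site_region[site]]]
            + eff_site[:, site_idx[site]]
            + eff_vint[:, vint_idx[vintage]]
        )
        alpha = _softmax(eta) * cfg.dm_concentration
        p = rng.dirichlet(np.maximum(alpha, 1e-8))
        depth = max(1, int(rng.poisson(cfg.library_size_dna)))
        counts[:, j] = rng.multinomial(depth, p)
    return CountTable(
        counts=pd.DataFrame(counts, index=ids, columns=sample_ids),
        marker=marker,
        taxonomy=pd.Series(taxonomy, index=ids),
    )


def _species_of(taxonomy: str) -> str:
    return taxonomy.split(";")[-1]


def _ferm_dna_relabund(
    fungal: CountTable, cfg: ScenarioConfig
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Per-fermentation DNA relative abundance, with a site-vintage mean
    fallback for fermentations whose must sample was dropped."""
    rel = fungal.counts / fungal.counts.sum(axis=0)
    ferms = cfg.rna_design()
    cols = {}
    for site, vintage, tank in ferms:
        sid = f"{site}-{vintage}-{tank}"
        if sid in rel.columns:
            cols[(site, vintage, tank)] = rel[sid]
        else:
            mates = [c for c in rel.columns if c.startswith(f"{site}-{vintage}-")]
            if not mates:
                raise ValidationError(
                    f"no must DNA sample available for fermentation {sid}"
                )
            cols[(site, vintage, tank)] = rel[mates].mean(axis=1)
    frame = pd.DataFrame(cols)
    return ferms, frame


def generate_expression_timeseries(
    cfg: ScenarioConfig, fungal: CountTable, return_truth: bool = False
):
    """Simulate per-timepoint 3' tag transcript tables for the RNA design.

    The inoculated S. cerevisiae contributes ~``inoculant_share`` of reads
    in every sample; a fixed grape (V. vinifera) organism contributes
    ``grape_share``; only ``frac_active_taxa`` of DNA-detected fungal taxa
    express at all.  For active taxa, RNA relative abundance is a linear
    function of the fermentation's must DNA relative abundance plus noise
    sized so the population R^2 equals ``dna_rna_r2``.  Site-informative
    inoculant genes carry site-specific log-fold effects constant across
    vintages and timepoints.

    With ``return_truth=True`` also returns the generator truth for the
    expression layer (active taxa, planted site-informative genes).
    """
    cfg.validate()
    if fungal.marker != "ITS":
        raise ValidationError("expression generator expects the fungal (ITS) table")
    rng = np.random.default_rng([cfg.seed, _STREAM_RNA])
    ferms, dna_rel = _ferm_dna_relabund(fungal, cfg)
    n_ferm = len(ferms)
    sites = cfg.sites
    site_idx = {s: i for i, s in enumerate(sites)}

    # which DNA-detected taxa are transcriptionally active
    n_active = int(round(cfg.frac_active_taxa * cfg.n_fungal_taxa))
    candidate_ids = list(fungal.counts.index[: cfg.n_fungal_taxa])
    active_ids: list[str] = []
    if n_active > 0:
        # the dominant taxon is always active; the rest drawn at random
        rest = rng.choice(
            np.array(candidate_ids[1:]), size=max(0, n_active - 1), replace=False
        )
        active_ids = [candidate_ids[0], *sorted(rest.tolist())]
    taxonomy = fungal.taxonomy
    active_species = [
        _species_of(taxonomy.loc[a]) if taxonomy is not None else a
        for a in active_ids
    ]

    # feature catalogue -------------------------------------------------
    gene_ids: list[str] = []
    organisms: list[str] = []
    for g in range(cfg.n_genes):
        gene_ids.append(f"YGENE{g + 1:04d}")
        organisms.append(INOCULANT_ORGANISM)
    for g in range(cfg.n_grape_genes):
        gene_ids.append(f"VVGENE{g + 1:04d}")
        organisms.append(GRAPE_ORGANISM)
    for a, sp in zip(active_ids, active_species):
        for g in range(cfg.genes_per_active_taxon):
            gene_ids.append(f"{a}_G{g + 1}")
            organisms.append(sp)
    rna_only = list(RNA_ONLY_ORGANISMS) if cfg.rna_only_share > 0 else []
    for k, sp in enumerate(rna_only):
        for g in range(cfg.genes_per_active_taxon):
            gene_ids.append(f"RNAONLY{k + 1}_G{g + 1}")
            organisms.append(sp)

    # inoculant gene model ---------------------------------------------
    n_tp = len(cfg.timepoints_hours)
    gene_base = rng.normal(0.0, 1.0, cfg.n_genes)
    gene_traj = rng.normal(0.0, cfg.gene_timepoint_sd, (cfg.n_genes, n_tp))
    planted = (
        sorted(
            rng.choice(cfg.n_genes, size=cfg.n_site_genes, replace=False).tolist()
        )
        if cfg.n_site_genes
        else []
    )
    gene_site_eff = np.zeros((cfg.n_genes, len(sites)))
    if planted:
        gene_site_eff[planted, :] = rng.normal(
            0.0, cfg.gene_effect_sd, (len(planted), len(sites))
        )
    grape_w = _softmax(rng.normal(0.0, 1.0, cfg.n_grape_genes)) if cfg.n_grape_genes else np.zeros(0)
    taxon_gene_w = {
        a: _softmax(rng.normal(0.0, 1.0, cfg.genes_per_active_taxon))
        for a in active_ids + [f"RNAONLY{k + 1}" for k in range(len(rna_only))]
    }

    # active-taxon share model ------------------------------------------
    non_sacch_budget = 1.0 - cfg.inoculant_share - cfg.grape_share
    rna_only_total = cfg.rna_only_share * len(rna_only)
    active_budget = max(non_sacch_budget - rna_only_total, 0.0)
    x = dna_rel.loc[active_ids].to_numpy() if active_ids else np.zeros((0, n_ferm))
    mean_x = x.mean(axis=1) if active_ids else np.zeros(0)
    var_x = x.var(axis=1, ddof=1) if n_ferm > 1 else np.zeros(len(active_ids))
    total_mean = mean_x.sum()
    share_k = (
        active_budget * mean_x / total_mean if total_mean > 0 else np.zeros(len(active_ids))
    )
    r2 = cfg.dna_rna_r2
    sigma = np.zeros(len(active_ids))
    for k in range(len(active_ids)):
        if var_x[k] <= 0:
            sigma[k] = 0.0
        elif r2 == 0:
            sigma[k] = math.sqrt(var_x[k])
        else:
            sigma[k] = math.sqrt(var_x[k] * (1 - r2) / r2)

    tables: dict[float, CountTable] = {}
    depth_cap = 0.5  # inoculant always retains a majority of reads
    for t, hours in enumerate(cfg.timepoints_hours):
        cols = {}
        for j, (site, vintage, tank) in enumerate(ferms):
            sid = f"{site}-{vintage}-{tank}-{hours:g}h"
            # latent non-Saccharomyces shares, linearly coupled to DNA
            z = np.zeros(len(active_ids))
            for k in range(len(active_ids)):
                if r2 == 0:
                    u = mean_x[k] + rng.normal(0.0, sigma[k])
                else:
                    u = x[k, j] + rng.normal(0.0, sigma[k])
                if mean_x[k] > 0:
                    z[k] = max(share_k[k] * u / mean_x[k], 0.0)
            overflow = z.sum() + rna_only_total
            if overflow > depth_cap:
                z *= (depth_cap - rna_only_total) / z.sum()
            # within-organism gene compositions
            eta = (
                gene_base
                + gene_traj[:, t]
                + gene_site_eff[:, site_idx[site]]
            )
            if cfg.n_genes:
                w_inoc = rng.dirichlet(
                    np.maximum(_softmax(eta) * cfg.gene_concentration, 1e-8)
                )
            else:
                w_inoc = np.zeros(0)
            inoc_share = 1.0 - cfg.grape_share - z.sum() - rna_only_total
            probs = [w_inoc * inoc_share, grape_w * cfg.grape_share]
            for k, a in enumerate(active_ids):
                probs.append(taxon_gene_w[a] * z[k])
            for k in range(len(rna_only)):
                probs.append(taxon_gene_w[f"RNAONLY{k + 1}"] * cfg.rna_only_share)
            p = np.concatenate(probs) if probs else np.zeros(0)
            if p.size == 0:
                cols[sid] = np.zeros(0, dtype=np.int64)
                continue
            p = np.maximum(p, 0)
            p = p / p.sum()
            depth = max(1, int(rng.poisson(cfg.library_size_rna)))
            cols[sid] = rng.multinomial(depth, p)
        tables[float(hours)] = CountTable(
            counts=pd.DataFrame(cols, index=gene_ids),
            marker="mRNA",
            organism=pd.Series(organisms, index=gene_ids),
        )
    if return_truth:
        expr_truth = {
            "active_taxa": list(active_ids),
            "active_species": list(active_species),
            "site_informative_genes": [f"YGENE{g + 1:04d}" for g in planted],
            "rna_only_organisms": rna_only,
        }
        return tables, expr_truth
    return tables


def generate_environment(cfg: ScenarioConfig) -> pd.DataFrame:
    """Site coordinates, climate and must-chemistry expectations.

    Precipitation and growing degree days are Gaussian-process draws over
    site coordinates (squared-exponential kernel, range ``env_spatial_range`` km),
    per vintage, so geographically close sites
    get similar climate by construction.  An infinite range collapses each
    field to a single shared value.  Chemistry columns are site-level
    expectations.  Returns one row per (site, vintage).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, _STREAM_ENV])
    sites = cfg.sites
    n = len(sites)
    if n < 3:
        logger.warning(
            "fewer than 3 sites: spatial-correlation structure cannot be checked"
        )
    lat = rng.uniform(38.0, 45.5, n)
    lon = rng.uniform(-123.5, -120.5, n)
    from .permstats import haversine_matrix  # local import to avoid cycle

    geo = haversine_matrix(np.column_stack([lat, lon]), ids=sites)
    if math.isinf(cfg.env_spatial_range):
        cov = np.ones((n, n))
    else:
        # smooth squared-exponential kernel: nearby sites share weather,
        # correlation decaying over env_spatial_range km
        cov = np.exp(-0.5 * (geo.values / cfg.env_spatial_range) ** 2)
    chol = np.linalg.cholesky(cov + 1e-8 * np.eye(n))

    def gp_field(mean: float, sd: float, lat_slope: float = 0.0) -> np.ndarray:
        """Latitudinal trend plus spatially correlated residual.

        West-coast growing-season climate is strongly latitude-structured
        (wetter north, warmer south); the deterministic trend plus the GP
        residual makes geographic and climate distances co-vary by
        construction.
        """
        if math.isinf(cfg.env_spatial_range):
            return np.full(n, mean + sd * rng.normal())
        trend = lat_slope * (lat - lat.mean())
        return mean + trend + sd * (chol @ rng.normal(size=n))

    chem_means = {
        "pH": (3.4, 0.12),
        "titratable_acidity": (6.5, 0.8),
        "malic_acid": (2.5, 0.6),
        "NOPA": (120.0, 30.0),
        "NH3": (60.0, 15.0),
    }
    site_chem = {k: m + s * rng.normal(size=n) for k, (m, s) in chem_means.items()}
    rows = []
    for vintage in cfg.vintages:
        precip = gp_field(450.0, 80.0, lat_slope=60.0)
        gdd = gp_field(1500.0, 120.0, lat_slope=-70.0)
        for i, site in enumerate(sites):
            rows.append(
                {
                    "site": site,
                    "vintage": vintage,
                    "region": cfg.site_region[site],
                    "latitude_deg": lat[i],
                    "longitude_deg": lon[i],
                    "precipitation_mm": precip[i],
                    "gdd": gdd[i],
                    **{k: site_chem[k][i] for k in chem_means},
                }
            )
    return pd.DataFrame(rows)


def _assemble_metadata(cfg: ScenarioConfig, env: pd.DataFrame) -> SampleMetadata:
    rng = np.random.default_rng([cfg.seed, _STREAM_ENV, 1])
    env_idx = env.set_index(["site", "vintage"])
    noise_scale = {
        "pH": 0.03,
        "titratable_acidity": 0.2,
        "malic_acid": 0.1,
        "NOPA": 8.0,
        "NH3": 4.0,
    }
    rows = {}

    def add_row(sid, site, vintage, tank, timepoint):
        e = env_idx.loc[(site, vintage)]
        row = {
            "site": site,
            "region": cfg.site_region[site],
            "vintage": vintage,
            "tank": tank,
            "timepoint_hours": timepoint,
            "latitude_deg": e["latitude_deg"],
            "longitude_deg": e["longitude_deg"],
            "precipitation_mm": e["precipitation_mm"],
            "gdd": e["gdd"],
        }
        for k, s in noise_scale.items():
            row[k] = e[k] + s * rng.normal()
        rows[sid] = row

    for site, vintage, tank in cfg.dna_design():
        add_row(f"{site}-{vintage}-{tank}", site, vintage, tank, np.nan)
    for site, vintage, tank in cfg.rna_design():
        for hours in cfg.timepoints_hours:
            add_row(
                f"{site}-{vintage}-{tank}-{hours:g}h", site, vintage, tank, float(hours)
            )
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    return SampleMetadata(frame)


def generate_study(cfg: ScenarioConfig) -> SyntheticStudy:
    """Generate a full synthetic study, deterministic given ``cfg.seed``."""
    cfg.validate()
    bacterial = generate_community_counts(cfg, "16S")
    fungal = generate_community_counts(cfg, "ITS")
    transcripts, expr_truth = generate_expression_timeseries(
        cfg, fungal, return_truth=True
    )
    env = generate_environment(cfg)
    metadata = _assemble_metadata(cfg, env)
    any_tp = next(iter(transcripts.values())) if transcripts else None
    truth = {
        "informative_taxa_site": (
            fungal.feature_ids[: cfg.n_fungal_taxa] if cfg.effect_sd_site > 0 else []
        ),
        "informative_taxa_region": (
            fungal.feature_ids[: cfg.n_fungal_taxa] if cfg.effect_sd_region > 0 else []
        ),
        "organelle_asvs": [f for f in bacterial.feature_ids if f.startswith("OASV")],
        "dna_rna_r2": cfg.dna_rna_r2,
        "seed": cfg.seed,
        **expr_truth,
    }
    all_features = set(fungal.feature_ids) | (
        set(any_tp.feature_ids) if any_tp is not None else set()
    )
    for key in ("active_taxa", "site_informative_genes"):
        unknown = set(truth[key]) - all_features
        if unknown:
            raise AssertionError(f"truth record lists unknown features: {unknown}")
    return SyntheticStudy(
        config=cfg,
        bacterial_counts=bacterial,
        fungal_counts=fungal,
        transcript_counts=transcripts,
        metadata=metadata,
        truth=truth,
    )
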