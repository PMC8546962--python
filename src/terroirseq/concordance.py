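"""DNA-RNA concordance: does must DNA abundance predict fermentation
transcription?

Pre-inoculation must DNA (one amplicon sample per tank) is paired with
each RNA timepoint of the same (site, vintage, tank) fermentation, and
RNA relative abundance is regressed on DNA relative abundance per
organism and timepoint (ordinary least squares on compositional counts).
Adjusted R^2 is reported, which can legitimately be negative when the
predictor carries no information.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import CountTable, SampleMetadata, ValidationError

_WS = re.compile(r"\s+")


def normalize_species(name: str) -> str:
    """Normalize a binomial species name for cross-assay matching:
    lower-case, abbreviation dots stripped, whitespace collapsed."""
    name = name.replace("_", " ").replace(".", "")
    return _WS.sub(" ", name).strip().lower()


@dataclass
class TaxonPairing:
    matched: dict[str, tuple[str, str]]  # species -> (dna feature, rna organism)
    dna_only: list[str]
    rna_only: list[str]
    genus_candidates: dict[str, list[str]]  # genus-level near-misses


@dataclass
class ConcordanceResult:
    organism: str
    timepoint_hours: float
    n_fermentations: int
    slope: float
    intercept: float
    r_squared: float  # adjusted
    p_value: float
    note: str | None = None


def _dna_species(table: CountTable) -> dict[str, str]:
    """feature id -> normalized species name, where species-resolvable."""
    if table.taxonomy is None:
        raise ValidationError("DNA table lacks taxonomy; cannot match species")
    out = {}
    for fid, lineage in table.taxonomy.items():
        last = lineage.replace(",", ";").split(";")[-1].strip()
        if len(last.split()) >= 2:  # binomial (or 'Genus sp...')
            out[fid] = normalize_species(last)
    return out


def _dna_genus(lineage: str) -> str:
    parts = [p.strip() for p in lineage.replace(",", ";").split(";") if p.strip()]
    return parts[-2].lower() if len(parts) >= 2 else ""


def match_taxa(dna: CountTable, rna: CountTable) -> TaxonPairing:
    """Pair DNA features with RNA organisms on normalized species names.

    DNA features resolved only to genus against an RNA species of that
    genus are reported as genus-level candidates, not matches.
    """
    if rna.organism is None:
        rna_species: dict[str, str] = {}
    else:
        rna_species = {
            normalize_species(org): org for org in rna.organism.unique()
        }
    dna_species = _dna_species(dna)
    dna_by_species = {sp: fid for fid, sp in dna_species.items()}
    matched = {
        sp: (dna_by_species[sp], rna_species[sp])
        for sp in set(dna_by_species) & set(rna_species)
    }
    dna_only = sorted(set(dna_by_species) - set(matched))
    rna_only = sorted(set(rna_species) - set(matched))
    genus_candidates: dict[str, list[str]] = {}
    if dna.taxonomy is not None:
        matched_genera = {sp.split()[0] for sp in matched}
        for fid, lineage in dna.taxonomy.items():
            if fid in dna_species:
                continue  # species-resolved already
            genus = _dna_genus(lineage)
            hits = [
                rna_species[sp]
                for sp in rna_species
                if sp.split()[0] == genus and genus not in matched_genera
            ]
            if hits:
                genus_candidates[fid] = sorted(hits)
    return TaxonPairing(
        matched=matched,
        dna_only=dna_only,
        rna_only=rna_only,
        genus_candidates=genus_candidates,
    )


def regress_dna_rna(
    dna_relabund,
    rna_relabund,
    organism: str = "",
    timepoint: float = float("nan"),
) -> ConcordanceResult:
    """OLS of RNA relative abundance on DNA relative abundance across
    fermentations, reporting slope, intercept, adjusted R^2 and the slope
    p-value.  A zero-variance predictor yields a flagged result."""
    x = np.asarray(dna_relabund, dtype=float)
    y = np.asarray(rna_relabund, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired abundance vectors required")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValidationError(
            f"need >= 3 fermentations with both measurements (got {n})"
        )
    if np.var(x) == 0:
        return ConcordanceResult(
            organism=organism,
            timepoint_hours=timepoint,
            n_fermentations=n,
            slope=float("nan"),
            intercept=float(np.mean(y)),
            r_squared=float("nan"),
            p_value=float("nan"),
            note="zero variance in DNA predictor",
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return ConcordanceResult(
        organism=organism,
        timepoint_hours=timepoint,
        n_fermentations=n,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared_adj),
        p_value=float(model.pvalues[1]),
    )


def _fermentation_of(meta: SampleMetadata) -> pd.Series:
    frame = meta.frame
    return frame["site"].astype(str) + "|" + frame["vintage"].astype(str) + "|" + frame[
        "tank"
    ].astype(str)


def paired_abundances(
    dna: CountTable,
    rna_tables: dict[float, CountTable],
    meta: SampleMetadata,
    dna_feature: str,
    rna_organism: str,
) -> dict[float, pd.DataFrame]:
    """Per timepoint, a (fermentation x [dna, rna]) relative-abundance
    frame pairing the pre-inoculation must sample with that tank's RNA
    sample."""
    ferm = _fermentation_of(meta)
    dna_rel = dna.counts / dna.counts.sum(axis=0)
    dna_by_ferm = {}
    for sid in dna.sample_ids:
        if sid in ferm.index and pd.isna(meta.frame.loc[sid, "timepoint_hours"]):
            dna_by_ferm[ferm.loc[sid]] = dna_rel.loc[dna_feature, sid]
    out = {}
    for tp, table in rna_tables.items():
        if table.organism is None:
            raise ValidationError("RNA table lacks organism annotation")
        rel = table.counts / table.counts.sum(axis=0)
        org_rel = rel[table.organism == rna_organism].sum(axis=0)
        rows = []
        for sid in table.sample_ids:
            if sid not in ferm.index:
                continue
            f = ferm.loc[sid]
            if f in dna_by_ferm:
                rows.append((f, dna_by_ferm[f], org_rel[sid]))
        out[tp] = pd.DataFrame(
            rows, columns=["fermentation", "dna", "rna"]
        ).set_index("fermentation")
    return out


def concordance_table(
    dna: CountTable,
    rna_tables: dict[float, CountTable],
    meta: SampleMetadata,
    species: str,
    timepoints=None,
) -> list[ConcordanceResult]:
    """Run the per-timepoint DNA-RNA regression for one species.

    ``species`` is matched against both assays by normalized name.
    """
    pairing = match_taxa(dna, next(iter(rna_tables.values())))
    key = normalize_species(species)
    if key not in pairing.matched:
        raise ValidationError(
            f"species {species!r} not detected by both assays; "
            f"matched species: {sorted(pairing.matched)}"
        )
    dna_feature, rna_org = pairing.matched[key]
    pairs = paired_abundances(dna, rna_tables, meta, dna_feature, rna_org)
    results = []
    for tp in sorted(pairs):
        if timepoints is not None and tp not in timepoints:
            continue
        frame = pairs[tp]
        results.append(
            regress_dna_rna(frame["dna"], frame["rna"], organism=rna_org, timepoint=tp)
        )
    return results


def detection_overlap(
    dna: CountTable, rna: CountTable, abundance_floor: float = 0.0
) -> dict:
    """Species detected by both assays, DNA only, and RNA only.

    Detection means a relative abundance above ``abundance_floor`` in at
    least one sample of that assay (organism counts are aggregated over
    each organism's genes for RNA).
    """
    def detected_dna() -> set[str]:
        species = _dna_species(dna)
        rel = dna.counts / dna.counts.sum(axis=0).replace(0, np.nan)
        hit = (rel > abundance_floor).any(axis=1)
        return {sp for fid, sp in species.items() if hit.get(fid, False)}

    def detected_rna() -> set[str]:
        if rna.organism is None:
            return set()
        rel = rna.counts / rna.counts.sum(axis=0).replace(0, np.nan)
        out = set()
        for org in rna.organism.unique():
            sub = rel[rna.organism == org].sum(axis=0)
            if (sub > abundance_floor).any():
                out.add(normalize_species(org))
        return out

    d, r = detected_dna(), detected_rna()
    return {
        "shared": sorted(d & r),
        "dna_only": sorted(d - r),
        "rna_only": sorted(r - d),
        "n_shared": len(d & r),
        "n_dna_only": len(d - r),
        "n_rna_only": len(r - d),
    }
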