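"""Consensus microbial/transcriptomic signatures of vineyard site and
region.

The core inference: summarize each gene's fermentation time series into
five attributes (mean, min, max, total, sd of library-size-normalized
counts), select variables (vita), fit a seeded random forest, compute
casewise permutation importance, average it over the training
fermentations of each class, retain genes with positive class-average
importance, and intersect the retained sets across many seeds.  A gene
qualifies if any of its five attributes qualifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CountTable, SampleMetadata, ValidationError
from .forest import (
    SeededForest,
    casewise_importance,
    evaluate,
    fit_forest,
    partition,
    vita_select,
)

logger = logging.getLogger(__name__)

ATTRIBUTES = ("mean", "min", "max", "total", "sd")


@dataclass
class ModelResult:
    seed: int
    target: str
    scheme: str
    hyperparameters: dict
    confusion_matrix: pd.DataFrame
    accuracy: float
    kappa: float
    global_importance: pd.Series
    casewise: pd.DataFrame  # training samples x selected features
    train_labels: pd.Series


@dataclass
class SignatureSet:
    """Per class, genes retained by every seeded model.

    ``signatures[class]`` maps each retained (gene, attribute) pair to its
    mean positive class-average casewise importance across seeds.
    """

    target: str
    scheme: str
    seeds: list[int]
    signatures: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)

    def genes(self, cls: str) -> set[str]:
        return {gene for gene, _ in self.signatures.get(cls, {})}

    def all_genes(self) -> set[str]:
        return set().union(*(self.genes(c) for c in self.signatures)) if self.signatures else set()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": cls, "gene": gene, "attribute": attr, "mean_local_importance": imp}
            for cls, sig in sorted(self.signatures.items())
            for (gene, attr), imp in sorted(sig.items())
        ]
        return pd.DataFrame(rows, columns=["class", "gene", "attribute", "mean_local_importance"])


def summarize_timeseries(
    rna_tables: dict[float, CountTable], meta: SampleMetadata
) -> pd.DataFrame:
    """Five-attribute summary of each gene's normalized time series.

    Counts are normalized by library size per sample; for each
    fermentation (site x vintage x tank) with >= 2 timepoints, each gene
    is summarized into mean, min, max, total and sample standard
    deviation (n-1 denominator) across timepoints.  Genes absent at a
    timepoint contribute 0.  Returns a fermentation x (gene, attribute)
    frame with MultiIndex columns.
    """
    if not rna_tables:
        raise ValidationError("no transcript tables supplied")
    frames = []
    for tp, table in sorted(rna_tables.items()):
        if table.n_features == 0:
            raise ValidationError(
                "transcript table is empty; signature stages need genes"
            )
        rel = table.counts / table.counts.sum(axis=0)
        rel.columns = pd.MultiIndex.from_tuples(
            [(c, float(tp)) for c in rel.columns], names=["sample", "timepoint"]
        )
        frames.append(rel)
    wide = pd.concat(frames, axis=1).fillna(0.0)
    meta_frame = meta.frame
    ferm_key = {}
    for sample in wide.columns.get_level_values("sample").unique():
        if sample not in meta_frame.index:
            raise ValidationError(f"RNA sample {sample!r} missing from metadata")
        row = meta_frame.loc[sample]
        ferm_key[sample] = f"{row['site']}|{row['vintage']}|{row['tank']}"
    rows = {}
    samples_by_ferm: dict[str, list] = {}
    for sample, ferm in ferm_key.items():
        samples_by_ferm.setdefault(ferm, []).append(sample)
    for ferm, samples in sorted(samples_by_ferm.items()):
        sub = wide.loc[:, wide.columns.get_level_values("sample").isin(samples)]
        if sub.shape[1] < 2:
            raise ValidationError(
                f"fermentation {ferm} has a single timepoint; sd undefined"
            )
        values = sub.to_numpy()
        rows[ferm] = np.concatenate(
            [
                values.mean(axis=1),
                values.min(axis=1),
                values.max(axis=1),
                values.sum(axis=1),
                values.std(axis=1, ddof=1),
            ]
        )
    genes = list(wide.index)
    columns = pd.MultiIndex.from_tuples(
        [(g, a) for a in ATTRIBUTES for g in genes], names=["gene", "attribute"]
    )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = columns
    return out.sort_index(axis=1)


def fermentation_labels(features: pd.DataFrame, meta: SampleMetadata, target: str) -> pd.Series:
    """Map fermentation ids ("site|vintage|tank") to a target label."""
    site_region = meta.frame.groupby("site")["region"].first()
    labels = {}
    for ferm in features.index:
        site, vintage, tank = ferm.split("|")
        if target == "site":
            labels[ferm] = site
        elif target == "region":
            labels[ferm] = site_region[site]
        elif target == "vintage":
            labels[ferm] = vintage
        else:
            raise ValidationError(f"unknown target {target!r}")
    return pd.Series(labels)


def fermentation_vintages(features: pd.DataFrame) -> pd.Series:
    return pd.Series({f: f.split("|")[1] for f in features.index})


def amplicon_features(table: CountTable) -> pd.DataFrame:
    """Amplicon model entry point: per-sample ASV relative abundances
    (samples x features), no time-series summarization."""
    rel = (table.counts / table.counts.sum(axis=0)).T
    rel.columns = pd.MultiIndex.from_tuples(
        [(g, "relabund") for g in rel.columns], names=["gene", "attribute"]
    )
    return rel


def run_model(
    features: pd.DataFrame,
    labels: pd.Series,
    scheme: str = "split70",
    seed: int = 0,
    n_trees: int = 500,
    tune: bool = False,
    select: bool = True,
    vintages: pd.Series | None = None,
    holdout_vintage: str | None = None,
    vita_trees: int = 100,
) -> ModelResult:
    """One seeded model: partition, (vita) select on training data only,
    fit, evaluate, and compute casewise importance on the training set."""
    X = features.to_numpy(dtype=float)
    y = labels.loc[features.index]
    train, test = partition(
        y,
        scheme,
        seed=seed,
        vintages=None if vintages is None else vintages.loc[features.index],
        holdout_vintage=holdout_vintage,
    )
    if select:
        selected = vita_select(X[train], y.iloc[train], seed=seed, n_trees=vita_trees)
        if selected.size == 0:
            logger.warning("vita selected no features; falling back to all")
            selected = np.arange(X.shape[1])
    else:
        selected = np.arange(X.shape[1])
    forest = fit_forest(
        X[train][:, selected], y.iloc[train], n_trees=n_trees, seed=seed, tune=tune
    )
    metrics = evaluate(forest, X[test][:, selected], y.iloc[test])
    case, global_imp = casewise_importance(
        forest, X[train][:, selected], y.iloc[train], seed=seed
    )
    sel_cols = features.columns[selected]
    case.index = features.index[train]
    case.columns = sel_cols
    return ModelResult(
        seed=seed,
        target=str(labels.name or "label"),
        scheme=scheme,
        hyperparameters={
            "n_trees": forest.n_trees,
            "mtry": forest.mtry,
            "sample_fraction": forest.sample_fraction,
            "min_node_size": forest.min_node_size,
        },
        confusion_matrix=metrics["confusion_matrix"],
        accuracy=metrics["accuracy"],
        kappa=metrics["kappa"],
        global_importance=pd.Series(global_imp, index=sel_cols),
        casewise=case,
        train_labels=y.iloc[train],
    )


def positive_class_features(result: ModelResult) -> dict[str, dict[tuple[str, str], float]]:
    """Per class, the (gene, attribute) pairs with positive average
    casewise importance over that class's training fermentations.

    Negative casewise values are retained through the averaging; only the
    class-average's sign is thresholded.
    """
    out: dict[str, dict[tuple[str, str], float]] = {}
    case = result.casewise
    for cls in result.train_labels.unique():
        rows = case.loc[result.train_labels == cls]
        class_mean = rows.mean(axis=0, skipna=True)
        positive = class_mean[class_mean > 0]
        out[cls] = {tuple(col): float(v) for col, v in positive.items()}
    return out


def consensus_signature(
    features: pd.DataFrame,
    labels: pd.Series,
    scheme: str = "split70",
    n_seeds: int = 100,
    base_seed: int = 0,
    n_trees: int = 500,
    tune: bool = False,
    vintages: pd.Series | None = None,
    holdout_vintage: str | None = None,
    vita_trees: int = 100,
) -> tuple[SignatureSet, list[ModelResult]]:
    """Strict-intersection consensus signatures across ``n_seeds`` models.

    A gene enters a class signature only if some attribute of it had
    positive class-average casewise importance in every one of the seeded
    models; its reported importance is the mean over seeds.  An empty
    intersection is a valid outcome.
    """
    if n_seeds < 2:
        raise ValidationError("consensus requires at least 2 seeds")
    seeds = [base_seed + s for s in range(n_seeds)]
    results = []
    per_seed_sets: list[dict[str, dict[tuple[str, str], float]]] = []
    for s in seeds:
        result = run_model(
            features,
            labels,
            scheme=scheme,
            seed=s,
            n_trees=n_trees,
            tune=tune,
            vintages=vintages,
            holdout_vintage=holdout_vintage,
            vita_trees=vita_trees,
        )
        results.append(result)
        per_seed_sets.append(positive_class_features(result))
    classes = sorted(set().union(*(set(d) for d in per_seed_sets)))
    signatures: dict[str, dict[tuple[str, str], float]] = {}
    for cls in classes:
        gene_sets = [
            {gene for gene, _ in d.get(cls, {})} for d in per_seed_sets
        ]
        common_genes = set.intersection(*gene_sets) if gene_sets else set()
        sig: dict[tuple[str, str], float] = {}
        for gene in common_genes:
            # report every attribute that was positive in all seeds; if
            # none is, the gene qualified via varying attributes and the
            # best-supported attribute is reported
            attr_support: dict[str, list[float]] = {}
            for d in per_seed_sets:
                for (g, attr), v in d.get(cls, {}).items():
                    if g == gene:
                        attr_support.setdefault(attr, []).append(v)
            full = {
                a: vs for a, vs in attr_support.items() if len(vs) == len(seeds)
            }
            chosen = full or {
                max(attr_support, key=lambda a: len(attr_support[a])): attr_support[
                    max(attr_support, key=lambda a: len(attr_support[a]))
                ]
            }
            for attr, vs in chosen.items():
                sig[(gene, attr)] = float(np.mean(vs))
        signatures[cls] = sig
    return (
        SignatureSet(
            target=str(labels.name or "label"),
            scheme=scheme,
            seeds=seeds,
            signatures=signatures,
        ),
        results,
    )


def organism_attribution(
    importance: pd.Series, gene_organism: pd.Series
) -> pd.Series:
    """Percent of total importance attributable to each organism.

    Negative importances are truncated to 0 before summation; the result
    sums to 100.
    """
    imp = importance.copy().astype(float)
    if isinstance(imp.index, pd.MultiIndex):
        imp = imp.groupby(level=0).sum()
    imp = imp.clip(lower=0.0)
    organisms = gene_organism.reindex(imp.index)
    if organisms.isna().any():
        missing = list(imp.index[organisms.isna()][:5])
        raise ValidationError(f"no organism mapping for gene(s) {missing}")
    totals = imp.groupby(organisms).sum()
    grand = totals.sum()
    if grand == 0:
        raise ValidationError(
            "all importances are zero; organism attribution undefined"
        )
    return totals / grand * 100.0
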