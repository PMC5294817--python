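"""Regulatory-score classification, score distributions, TF co-occurrence
and genotype-dependent binding summaries.

Variants carry an ordinal regulatory-evidence category (1a..6).  Categories
1a-1f, 2a, 2b and 2c denote variants likely to affect transcription-factor
binding; classification uses that explicit category set, never numeric
parsing of the labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LIKELY_CATEGORIES = ("1a", "1b", "1c", "1d", "1e", "1f", "2a", "2b", "2c")
OTHER_CATEGORIES = ("3a", "3b", "4", "5", "6")
ALL_CATEGORIES = LIKELY_CATEGORIES + OTHER_CATEGORIES


@dataclass(frozen=True)
class RegScoreRecord:
    snp_id: str
    category: str
    bound_tfs: frozenset = field(default_factory=frozenset)
    eqtl_genes: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "bound_tfs", frozenset(self.bound_tfs))
        object.__setattr__(self, "eqtl_genes", tuple(self.eqtl_genes))


@dataclass
class Classification:
    likely: list
    other: list
    rejected: list

    @property
    def n_likely(self) -> int:
        return len(self.likely)

    @property
    def n_other(self) -> int:
        return len(self.other)

    @property
    def fraction_likely(self) -> float:
        total = self.n_likely + self.n_other
        return self.n_likely / total if total else float("nan")


def classify_likely_affecting(records: Iterable[RegScoreRecord]) -> Classification:
    """Partition records into likely-to-affect-binding (categories 1a-2c) vs other.

    Records with an unknown category are rejected with a logged warning and
    returned separately; they count in neither partition.
    """
    likely, other, rejected = [], [], []
    for rec in records:
        if rec.category in LIKELY_CATEGORIES:
            likely.append(rec)
        elif rec.category in OTHER_CATEGORIES:
            other.append(rec)
        else:
            logger.warning("unknown regulatory category %r for %s", rec.category, rec.snp_id)
            rejected.append(rec)
    return Classification(likely, other, rejected)


class ScoreDistribution:
    """Counts of regulatory categories per labelled SNP set.

    ``frame`` is indexed by category with one column per label.  An optional
    ``universe`` maps label -> size of the SNP set the counts were drawn from
    (the column total may be smaller when only high-evidence categories are
    tabulated).
    """

    def __init__(self, frame: pd.DataFrame, universe: Optional[Mapping[str, int]] = None):
        self.frame = frame
        self.universe = dict(universe or {})

    def total(self, label: str) -> int:
        return int(self.frame[label].sum())

    def likely_total(self, label: str) -> int:
        rows = [c for c in LIKELY_CATEGORIES if c in self.frame.index]
        return int(self.frame.loc[rows, label].sum())

    def likely_fraction(self, label: str, denominator: Optional[int] = None) -> float:
        if denominator is None:
            denominator = self.universe.get(label, self.total(label))
        return self.likely_total(label) / denominator

    @classmethod
    def from_records(
        cls,
        snp_sets: Mapping[str, Iterable[str]],
        records: Iterable[RegScoreRecord],
        universe: Optional[Mapping[str, int]] = None,
    ) -> "ScoreDistribution":
        by_snp = {}
        for rec in records:
            by_snp.setdefault(rec.snp_id, rec.category)
        labels = list(snp_sets)
        if len(set(labels)) != len(labels):
            raise ValueError("snp-set labels must be distinct")
        data = {label: [0] * len(ALL_CATEGORIES) for label in labels}
        cat_index = {c: i for i, c in enumerate(ALL_CATEGORIES)}
        for label in labels:
            for snp in set(snp_sets[label]):
                cat = by_snp.get(snp)
                if cat in cat_index:
                    data[label][cat_index[cat]] += 1
        frame = pd.DataFrame(data, index=list(ALL_CATEGORIES))
        if universe is None:
            universe = {label: len(set(snp_sets[label])) for label in labels}
        return cls(frame, universe)

    @classmethod
    def from_counts_tsv(cls, path) -> "ScoreDistribution":
        """Load a counts table: first column 'category', remaining columns are
        labels; an optional row with category 'universe' holds set sizes."""
        frame = pd.read_csv(path, sep="\t", dtype={"category": str}).set_index("category")
        universe = None
        if "universe" in frame.index:
            universe = frame.loc["universe"].astype(int).to_dict()
            frame = frame.drop(index="universe")
        return cls(frame.astype(int), universe)

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        if self.universe:
            out.loc["universe"] = pd.Series(self.universe)
        out.index.name = "category"
        out.to_csv(path, sep="\t")


def score_distribution(
    snp_sets: Mapping[str, Iterable[str]],
    records: Iterable[RegScoreRecord],
) -> ScoreDistribution:
    """Tabulate category counts for each labelled SNP set."""
    return ScoreDistribution.from_records(snp_sets, records)


def tf_cooccurrence(
    snp_ids: Iterable[str], records: Iterable[RegScoreRecord]
) -> pd.DataFrame:
    """Frequency table TF -> number of SNPs whose site that TF binds.

    A TF listed more than once for one SNP counts once for that SNP (set
    semantics).  Sorted by descending count, ties broken lexicographically;
    this is the table a TF wordcloud would be drawn from.
    """
    wanted = set(snp_ids)
    counts: dict[str, set] = {}
    for rec in records:
        if rec.snp_id in wanted:
            for tf in rec.bound_tfs:
                counts.setdefault(tf, set()).add(rec.snp_id)
    rows = sorted(
        ((tf, len(snps)) for tf, snps in counts.items()),
        key=lambda t: (-t[1], t[0]),
    )
    return pd.DataFrame(rows, columns=["tf", "n_snps"])


GENOTYPE_CLASSES = {0: "ref_hom", 1: "het", 2: "alt_hom"}


@dataclass
class GenotypeBindingSummary:
    """Per-genotype-class binding-signal summary at one site.

    ``monotonic`` reports whether class means are ordered with alternate
    allele dosage: "decreasing" (signal lost with the alternate allele),
    "increasing", "flat", or "undefined" when fewer than two classes are
    observed.
    """

    classes: pd.DataFrame  # index ref_hom/het/alt_hom; columns n, mean, sd
    monotonic: str

    def to_tsv(self, path) -> None:
        out = self.classes.copy()
        out.index.name = "genotype_class"
        out["monotonic"] = self.monotonic
        out.to_csv(path, sep="\t")


def binding_by_genotype(
    genotypes: Mapping[str, int], signals: Mapping[str, float]
) -> GenotypeBindingSummary:
    """Summarize binding signal by genotype class (alt-allele dosage 0/1/2)."""
    for sample in signals:
        if sample not in genotypes:
            raise ValueError(f"sample {sample!r} has a signal but no genotype")
    by_class: dict[str, list[float]] = {}
    for sample, sig in signals.items():
        g = genotypes[sample]
        if g not in GENOTYPE_CLASSES:
            raise ValueError(f"genotype {g!r} for sample {sample!r} not in {{0,1,2}}")
        by_class.setdefault(GENOTYPE_CLASSES[g], []).append(float(sig))
    rows = []
    for dosage in (0, 1, 2):
        name = GENOTYPE_CLASSES[dosage]
        vals = by_class.get(name, [])
        rows.append(
            {
                "n": len(vals),
                "mean": float(np.mean(vals)) if vals else float("nan"),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    frame = pd.DataFrame(rows, index=[GENOTYPE_CLASSES[d] for d in (0, 1, 2)])
    means = [frame.loc[GENOTYPE_CLASSES[d], "mean"] for d in (0, 1, 2)
             if frame.loc[GENOTYPE_CLASSES[d], "n"] > 0]
    if len(means) < 2:
        mono = "undefined"
    elif all(a > b for a, b in zip(means, means[1:])):
        mono = "decreasing"
    elif all(a < b for a, b in zip(means, means[1:])):
        mono = "increasing"
    elif all(a == b for a, b in zip(means, means[1:])):
        mono = "flat"
    else:
        mono = "non-monotone"
    return GenotypeBindingSummary(classes=frame, monotonic=mono)
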