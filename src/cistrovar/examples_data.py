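"""Bundled worked-example tables at the scale of a full genome-wide analysis.

Three small TSVs ship with the package:

* ``regulome_score_counts.tsv`` — regulatory-evidence category counts (the
  high-evidence classes 1a..2c) for three nested SNP sets from a full-scale
  cistrome-GWAS integration, with each set's universe size;
* ``dr3_snp_annotations.tsv`` — trait-associated SNPs found inside DR3
  motifs under binding peaks, with in-motif positions;
* ``analysis_scale_counts.tsv`` — headline set sizes of the same analysis
  (universe, under-peak, significant-SNP and shared-loci counts).

They serve as README/acceptance worked examples; nothing in the pipeline
depends on them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotation import ScoreDistribution


def _path(name: str):
    return resources.files("cistrovar").joinpath("examples", name)


def load_score_counts() -> ScoreDistribution:
    with resources.as_file(_path("regulome_score_counts.tsv")) as p:
        return ScoreDistribution.from_counts_tsv(p)


def load_dr3_annotations() -> pd.DataFrame:
    with resources.as_file(_path("dr3_snp_annotations.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_analysis_counts() -> dict:
    with resources.as_file(_path("analysis_scale_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["name"], df["count"].astype(int)))


def default_pwm_path():
    return resources.files("cistrovar").joinpath("data", "dr3_half_site.pwm")
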