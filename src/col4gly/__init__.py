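"""Genotype-phenotype analysis of collagen IV Gly substitutions.

Library layout mirrors the analysis stages:

``chain_model``   alpha-chain domain architecture and position classes
``variants``      HGVS-like parsing and molecular feature annotation
``splice``        maximum-entropy splice screening
``survival``      family aggregation, Kaplan-Meier, log-rank, Cox
``haematuria``    case-control logistic stage
``population``    substitution-rate expectation, binomial test, prevalence
``synthetic``     seeded generators for every stage's inputs
``pipeline``      orchestration, manifests, reports
"""

from importlib import resources

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a bundled data file (synthetic architectures, rate table...)."""
    return resources.files("col4gly") / "data" / name
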