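import numpy as np
import pandas as pd
import pytest

import rvburden as rv


@pytest.fixture(scope="session")
def confounded_config() -> rv.SimConfig:
    """Two strata differing in baseline frequency and case:control ratio.

    Stratum A: high baseline, control-heavy; stratum B: low baseline,
    case-heavy.  A null gene then shows a crude odds ratio away from 1 while
    the stratum-adjusted estimate stays near 1.
    """
    return rv.SimConfig(
        strata=[
            rv.StratumSpec("A", n_cases=500, n_controls=1500, freq_multiplier=4.0),
            rv.StratumSpec("B", n_cases=1500, n_controls=500, freq_multiplier=1.0),
        ],
        genes=[
            rv.GeneSpec("NULLG", control_freq=0.004, odds_ratio=1.0),
            rv.GeneSpec("RISKG", control_freq=0.004, odds_ratio=3.0),
        ],
        n_missense_per_gene=8,
        seed=20240917,
    )


@pytest.fixture(scope="session")
def confounded_bundle(confounded_config) -> rv.CohortBundle:
    return rv.simulate_cohort(confounded_config)


@pytest.fixture(scope="session")
def classified_bundle(confounded_bundle):
    """(bundle, retained manifest, called genotypes, classification table)."""
    from rvburden.calling import apply_genotype_acceptance, apply_sample_qc

    manifest, _ = apply_sample_qc(confounded_bundle.manifest)
    accepted, _ = apply_genotype_acceptance(confounded_bundle.evidence)
    key = ["sample_id", "variant_id"]
    genotypes = confounded_bundle.genotypes.merge(accepted[key], on=key, how="inner")
    genotypes = genotypes[genotypes["sample_id"].isin(manifest["sample_id"])]
    classified = rv.classify_variants(confounded_bundle.variants)
    return confounded_bundle, manifest, genotypes, classified


def missense_matrix(bundle: rv.CohortBundle, manifest: pd.DataFrame) -> pd.DataFrame:
    """Wide sample x variant genotype matrix over the missense variants."""
    mis = bundle.genotypes[bundle.genotypes["variant_id"].str.contains("_mis")]
    wide = mis.pivot_table(index="sample_id", columns="variant_id", values="gt")
    return wide.reindex(manifest["sample_id"]).fillna(0.0)
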