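import numpy as np
import pytest

from burdensim.keys import VariantKey
from burdensim.types import (
    AncestryLabel,
    CohortGenotypeMatrix,
    PopulationVariantStats,
    VariantAnnotation,
)


def make_cohort(
    dosage,
    ancestry_labels=None,
    dp=None,
    gq=None,
    ab=None,
    sor=None,
    excess_het=None,
    variants=None,
    spacing=100,
):
    """Build a toy cohort from a (n_variants, n_samples) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_var, n_smp = dosage.shape
    samples = [f"S{j:03d}" for j in range(n_smp)]
    if ancestry_labels is None:
        ancestry = {s: AncestryLabel.EUR for s in samples}
    else:
        ancestry = {s: lbl for s, lbl in zip(samples, ancestry_labels)}
    if variants is None:
        variants = [
            VariantKey("1", 1000 + i * spacing, "A", "T") for i in range(n_var)
        ]
    return CohortGenotypeMatrix(
        samples=samples,
        ancestry=ancestry,
        variants=variants,
        dosage=dosage,
        dp=dp,
        gq=gq,
        ab=ab,
        sor=np.ones(n_var) if sor is None else np.asarray(sor, dtype=float),
        excess_het=excess_het,
    )


def make_db(entries, qc_pass=True, covered=True, n_called=100_000):
    """entries: {VariantKey: {AncestryLabel: (ac, an)}} -> db mapping."""
    db = {}
    for key, pops in entries.items():
        rec = PopulationVariantStats(
            key=key, qc_pass=qc_pass, covered=covered, n_called_individuals=n_called
        )
        for pop, (ac, an) in pops.items():
            rec.ac[pop] = ac
            rec.an[pop] = an
            rec.hom_alt[pop] = 0
        db[key] = rec
    return db


def make_annotation(key, gene="GENE", consequence="missense", cadd=30.0, af=None, domain=None):
    return VariantAnnotation(
        key=key,
        gene_id=gene,
        consequence=consequence,
        cadd_phred=cadd,
        af_pop=af or {},
        domain_id=domain,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
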