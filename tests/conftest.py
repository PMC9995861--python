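import numpy as np
import pytest

from hlapocket.association import fit_additive
from hlapocket.cohort import CASE, CONTROL, GenotypeTable, SubjectRecord, \
    allele_dosages
from hlapocket.registry import Allele, parse_allele
from hlapocket.simulate import GeneratorConfig, gad_like_config, generate


def mk_subject(i, status, stratum=None, **genotypes):
    """Build a SubjectRecord from gene=('ff:ff','ff:ff') keyword pairs."""
    g = {gene: (parse_allele(a1, gene=gene), parse_allele(a2, gene=gene))
         for gene, (a1, a2) in genotypes.items()}
    return SubjectRecord(f"S{i:04d}", status, stratum, g)


def mk_table(specs):
    """specs: list of (status, {gene: (a1, a2)}) tuples."""
    subjects = [mk_subject(i, status, None, **genos)
                for i, (status, genos) in enumerate(specs)]
    genes = sorted({g for _s, genos in specs for g in genos})
    return GenotypeTable(subjects, genes)


@pytest.fixture
def make_table():
    return mk_table


def dp_only_config(effects=(), n_subjects=849, missingness=True):
    """The study-like config trimmed to the DP loci (the non-DP tables do not
    enter the DP analyses; dropping them keeps simulations fast)."""
    cfg = gad_like_config(effects=list(effects))
    cfg.allele_freqs = {label: {} for label, _w in cfg.strata}
    if not missingness:
        cfg.missingness = {}
    cfg.n_subjects = n_subjects
    return cfg


@pytest.fixture(scope="session")
def null_pvalues():
    """Wald p-values for a common-allele dosage test on 2,000 null cohorts
    (no planted effects), shared by the calibration checks."""
    cfg = dp_only_config(effects=(), missingness=False)
    allele = parse_allele("DPB1*04:01")
    seeds = np.random.SeedSequence(1234).generate_state(2000) % (2**31)
    pvals = []
    for s in seeds:
        table = generate(cfg, seed=int(s)).table
        subs, dosage = allele_dosages(table, "DPB1", allele)
        status = [1 if x.is_case else 0 for x in subs]
        pvals.append(fit_additive(dosage, status).p)
    return np.array(pvals)
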