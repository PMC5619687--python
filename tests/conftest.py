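
import pytest

from transtwas import synthdata as sd


@pytest.fixture(scope="session")
def published():
    return sd.load_published_tables()


@pytest.fixture(scope="session")
def tiny_archs():
    # 8 genes: g0000 risk-increasing, g0001 protective, rest null
    gammas = [0.4, -0.4] + [0.0] * 6
    return sd.standard_architectures(8, snps_per_gene=6, h2_cis=0.5,
                                     gamma=gammas)


@pytest.fixture(scope="session")
def tiny_panel(tiny_archs):
    return sd.simulate_reference_panel(300, tiny_archs, ld_block_rho=0.3,
                                       seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_archs, tiny_panel):
    spec = sd.CohortSpec("tiny", sd.AncestrySpec("popA", fst=0.02),
                         n_cases=400, n_controls=400,
                         monomorphic_snps=("g0002_v0",))
    return sd.simulate_cohort(spec, tiny_archs, tiny_panel.variants,
                              ld_block_rho=0.3, seed=12)


def er_negative_neff(published):
    """Effective sample sizes of the four ER-negative discovery studies."""
    from transtwas.metacombine import effective_n
    out = {}
    for study in ("AABC", "BPC3", "ROOT", "SBCGS"):
        cases, controls = published.counts(study, "er_negative")
        out[study] = effective_n(cases, controls)
    return out


def overall_neff(published):
    from transtwas.metacombine import effective_n
    out = {}
    for study in ("AABC", "CGEMS", "ROOT", "SBCGS"):
        cases, controls = published.counts(study, "overall")
        out[study] = effective_n(cases, controls)
    return out
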