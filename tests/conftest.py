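import dataclasses

import pytest

from syntropyr import mossbauer, synthetic, thermo


@pytest.fixture(scope="session")
def reactions():
    return thermo.standard_reactions()


@pytest.fixture(scope="session")
def feasibility_conditions():
    """The syntrophic feasibility argument's condition set: 5 mM H2S,
    1 uM zero-valent sulfur, 1e-4 bar H2, 25 degC."""
    return thermo.ConditionSet(
        activities={"H2S": 5e-3, "[S0]": 1e-6, "H2": 1e-4}
    )


@pytest.fixture(scope="session")
def j5_noiseless():
    params = dataclasses.replace(synthetic.scenario_presets()["J5"], noise=0.0)
    return synthetic.generate(params)


@pytest.fixture(scope="session")
def abiotic_sites():
    """Mackinawite singlet + broad FeSx sextet at the abiotic-control split."""
    return mossbauer.sites_for_composition({"FeS": 0.64, "FeSx": 0.36})


def perturbed_template(sites, dv=0.04, db=1.05):
    """Shift starting values so fits do not begin at the generating truth."""
    return [
        dataclasses.replace(
            s,
            center_shift=s.center_shift + dv,
            hyperfine_field=s.hyperfine_field * db if s.kind == "sextet" else 0.0,
        )
        for s in sites
    ]
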