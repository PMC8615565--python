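import pytest

import gclogic as g
from gclogic.lesions import (
    HIGH_IMPACT_CLASSES,
    Lesion,
    PerturbationSet,
    default_mapping,
    genotype_to_perturbations,
)
from gclogic.pipeline import analyze_patient, build_patient_model


@pytest.fixture(scope="session")
def gc_network():
    return g.build_gc_network()


@pytest.fixture(scope="session")
def wt_profile(gc_network):
    """Wild-type profile over all eight input combinations."""
    return g.wild_type_profile(gc_network)


@pytest.fixture(scope="session")
def fixture_reports(gc_network, wt_profile):
    """Full pipeline results for the nine worked patient genotypes."""
    out = {}
    for fx in g.fixture_patients():
        pset = genotype_to_perturbations(fx.model_id, fx.lesions, network=gc_network)
        out[fx.model_id] = analyze_patient(pset, gc_network, wt_profile)
    return out


@pytest.fixture(scope="session")
def clamp_model(gc_network):
    """Build a patient model directly from a clamp dict (no genotype)."""

    def build(clamps, model_id="m"):
        return build_patient_model(
            gc_network, PerturbationSet(model_id, clamps), model_id
        )

    return build


def random_genotype(rng, max_lesions=6):
    """Draw a random high-impact genotype over the default mapping table."""
    genes = sorted({r.gene for r in default_mapping()})
    classes = sorted(HIGH_IMPACT_CLASSES)
    k = rng.randint(1, max_lesions)
    return [
        Lesion("rand", rng.choice(genes), rng.choice(classes))
        for _ in range(k)
    ]
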