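import pandas as pd
import pytest
from hypothesis import settings

from moaconsensus import load_binmap, load_policy

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def binmap():
    return load_binmap()


@pytest.fixture(scope="session")
def policy():
    return load_policy()


@pytest.fixture()
def chem_table():
    """Four chemicals spanning all-agree N/S/U plus a no-consensus pattern."""
    rows = [
        # code NNNN
        dict(id="c1", smiles="CCO", test_label="Narcosis", aster_label="Nonpolar narcosis",
             oasis_label="Base surface narcotics",
             verhaar_label="Class 1 (narcosis or baseline toxicity)"),
        # code SSSS
        dict(id="c2", smiles="O=Cc1ccccc1", test_label="Reactivity", aster_label="Reactive",
             oasis_label="Reactive unspecified", verhaar_label="Class 3 (unspecific reactivity)"),
        # code UUUU
        dict(id="c3", smiles="c1ccccc1", test_label="", aster_label="", oasis_label="",
             verhaar_label=""),
        # code NUNS
        dict(id="c4", smiles="CC(C)O", test_label="Narcosis", aster_label="",
             oasis_label="Narcotic amines", verhaar_label="Class 4 (compounds and groups of compounds acting by a specific mechanism)"),
    ]
    return pd.DataFrame(rows)


@pytest.fixture()
def study_table():
    rows = [
        dict(id="c1", species="P. promelas", trophic_level="fish", endpoint="LC50",
             duration_h=96.0, effect_mg_L=12.0),
        dict(id="c2", species="P. promelas", trophic_level="fish", endpoint="LC50",
             duration_h=48.0, effect_mg_L=0.9),
        dict(id="c2", species="D. magna", trophic_level="invertebrate", endpoint="EC50",
             duration_h=48.0, effect_mg_L=0.05),
        dict(id="c2", species="R. subcapitata", trophic_level="algae", endpoint="EC50",
             duration_h=72.0, effect_mg_L=3.0),
        dict(id="c2", species="O. mykiss", trophic_level="fish", endpoint="LC50",
             duration_h=120.0, effect_mg_L=1.5),  # outside acute window
        dict(id="c3", species="D. magna", trophic_level="invertebrate", endpoint="EC50",
             duration_h=24.0, effect_mg_L=30.0),
    ]
    return pd.DataFrame(rows)
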