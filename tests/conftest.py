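import numpy as np
import pandas as pd
import pytest

from granufuse import (GeneratorSpec, MaterialDB, MaterialRecord,
                       PROPERTY_COLUMNS, generate_material_db)

BASE_PROPS = {
    "Da": 0.45, "Dc": 0.55, "Dt": 1.50, "porosity": 0.70, "Ie": 0.40,
    "IC": 18.0, "Icd": 8.0, "IH": 1.222, "angle": 35.0, "flow_time": 10.0,
    "HR": 3.5, "H": 2.0, "pf": 20.0, "Itheta": 0.02,
    "D10": 20.0, "D50": 80.0, "D90": 200.0, "span": 2.25,
}


def make_record(name, spec="", **overrides):
    """A physically consistent record with selected properties overridden."""
    props = dict(BASE_PROPS)
    props.update(overrides)
    if "IH" not in overrides and {"Da", "Dc"} & set(overrides):
        props["IH"] = props["Dc"] / props["Da"]
    vec = np.array([props[c] for c in PROPERTY_COLUMNS], dtype=float)
    return MaterialRecord(name, spec, vec)


@pytest.fixture
def toy_db():
    """Small handcrafted database exercising all three matching rules."""
    db = MaterialDB()
    db.add(make_record("MCC", "PH101", D10=30, D50=65, D90=160, span=2.0))
    db.add(make_record("MCC", "PH102", D10=45, D50=110, D90=260,
                       span=1.955, Da=0.32, Dc=0.40, Dt=1.56))
    db.add(make_record("lactose", "110M", D50=60.0, D10=15, D90=150,
                       span=2.25, Da=0.62, Dc=0.74, Dt=1.54))
    db.add(make_record("lactose", "200M", D50=100.0, D10=25, D90=250,
                       span=2.25, Da=0.58, Dc=0.70, Dt=1.54))
    db.add(make_record("magnesium stearate", "", D10=1.21, D50=2.82,
                       D90=5.32, span=1.457, Da=0.25, Dc=0.35, Dt=1.09))
    return db


@pytest.fixture
def synth_db():
    return generate_material_db(GeneratorSpec(n_materials=10, seed=42))


@pytest.fixture
def property_matrix(synth_db):
    return synth_db.property_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
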