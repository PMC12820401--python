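"""Shared fixtures: toy databases, diets and models, all generated in-process."""

from __future__ import annotations

import pytest

from dietforge.diet_builder import build_diet
from dietforge.fixtures import (
    FixtureSpec,
    make_toy_food_db,
    make_toy_wbm,
    table2_equivalents_consumed,
)


@pytest.fixture(scope="session")
def toy_db():
    return make_toy_food_db(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def defect_db():
    return make_toy_food_db(FixtureSpec(seed=1, defect="missing_essential_metabolite"))


@pytest.fixture()
def toy_model():
    # function-scoped: most tests mutate bounds or add reactions
    return make_toy_wbm()


@pytest.fixture(scope="session")
def equivalents():
    return table2_equivalents_consumed()


@pytest.fixture(scope="session")
def diet1(toy_db, equivalents):
    return build_diet(equivalents, toy_db, "diet1")
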