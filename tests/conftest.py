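import pandas as pd
import pytest

from fvgdr.groups import FoodGroup, FoodMapping


@pytest.fixture()
def mapping() -> FoodMapping:
    """Small illustrative item -> group mapping used across tests."""
    m = FoodMapping(country_tag="test")
    m.add("carrot", FoodGroup.VA_VEG, True)
    m.add("pumpkin", FoodGroup.VA_VEG, False)
    m.add("spinach", FoodGroup.DGLV, True)
    m.add("cabbage", FoodGroup.OTHER_VEG, True)
    m.add("mushroom", FoodGroup.OTHER_VEG, False)
    m.add("mango", FoodGroup.VA_FRUIT, True)
    m.add("orange", FoodGroup.CITRUS, True)
    m.add("apple", FoodGroup.OTHER_FRUIT, True)
    return m


@pytest.fixture()
def mapping_csv(tmp_path, mapping):
    path = tmp_path / "mapping.csv"
    mapping.to_frame().to_csv(path, index=False)
    return path


def write_csv(path, text: str):
    path.write_text(text.strip() + "\n")
    return path
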