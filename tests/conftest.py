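import numpy as np
import pytest

#: every composition code printed with its fingerprint m/z in the study,
#: used by the mass-model exactness tests
PRINTED_MZ = {
    "Hex4a1": 731, "Hex4a2": 773, "Hex5a1": 893, "Hex5a2": 935,
    "Hex6a1": 1055, "Hex3a1": 569, "Pen4": 569, "Hex4": 689, "Hex5": 851,
    "Hex7a1": 1217, "Hex7a2": 1259, "Hex8a1": 1379, "Hex8a2": 1421,
    "Pen3U1": 613, "Pen3U1a1": 655, "Pen4a1": 611, "Pen4a2": 653,
    "Pen4U1m1": 759, "Pen4U1m1a1": 801, "Pen5a1": 743, "Pen5U1m1a1": 933,
    "XXFGa1": 1435, "XLFGa1": 1597, "XXG": 791, "XLG": 953, "GFG": 967,
    "XFG": 1099, "XLXG": 1247, "XLXGa1": 1289, "XXFG": 1393,
    "XXFGa2": 1477, "XLFGa2": 1639, "XXXG": 1085, "XLLGa1": 1451,
}


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
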