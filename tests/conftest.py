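import pytest

from keggtuner import FixtureSpec, make_synthetic_pathway

MINIMAL_KGML = """<?xml version="1.0" encoding="UTF-8"?>
<pathway name="path:syn00001" org="syn" number="00001" title="Minimal">
  <entry id="1" name="hsa:10" type="gene">
    <graphics name="A" x="10" y="10" width="46" height="17" type="rectangle"
      fgcolor="#000000" bgcolor="#BFFFBF"/>
  </entry>
  <entry id="2" name="hsa:20" type="gene">
    <graphics name="B" x="90" y="10" width="46" height="17" type="rectangle"
      fgcolor="#000000" bgcolor="#BFFFBF"/>
  </entry>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
"""


@pytest.fixture
def minimal_kgml():
    return MINIMAL_KGML


@pytest.fixture
def planted_pathway():
    """Default fixture: 3 PCP chains, 7 reversed bindings, 2 groups."""
    return make_synthetic_pathway(FixtureSpec(seed=42))


@pytest.fixture
def clean_pathway():
    """Fixture with no planted inconsistencies."""
    spec = FixtureSpec(n_pcp_motifs=0, n_reversed_bindings=0, n_groups=0,
                       n_duplicated_entries=0, seed=5)
    return make_synthetic_pathway(spec)
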