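import io

import pytest

from tissuescore.ihc import StainingTable
from tissuescore.ontology import parse_obo

TOY_OBO = """\
format-version: 1.2
ontology: toy-tissues

[Term]
id: T:root
name: whole body

[Term]
id: T:nervous
name: nervous system
is_a: T:root

[Term]
id: T:brain
name: brain
synonym: "encephalon" EXACT []
is_a: T:nervous

[Term]
id: T:cortex
name: cerebral cortex
is_a: T:brain

[Term]
id: T:liver
name: Liver
synonym: "hepatic tissue" EXACT []
is_a: T:root

[Term]
id: T:heart
name: heart
is_a: T:root

[Term]
id: T:obsolete
name: outdated tissue
is_obsolete: true
"""

# diamond: d -> b, d -> c, b -> a, c -> a
DIAMOND_OBO = """\
format-version: 1.2
ontology: diamond

[Term]
id: D:a
name: a

[Term]
id: D:b
name: b
is_a: D:a

[Term]
id: D:c
name: c
is_a: D:a

[Term]
id: D:d
name: d
is_a: D:b
is_a: D:c
"""


@pytest.fixture(scope="session")
def toy_dag():
    return parse_obo(io.StringIO(TOY_OBO))


@pytest.fixture(scope="session")
def diamond_dag():
    return parse_obo(io.StringIO(DIAMOND_OBO))


def random_staining_table(rng, protein="p", n_antibodies=None, n_tissues=None):
    """A random complete staining matrix over the allowed ordinal values."""
    A = n_antibodies or int(rng.integers(2, 6))
    T = n_tissues or int(rng.integers(3, 11))
    values = rng.choice([0, 1, 3, 6], size=(A, T))
    return StainingTable(
        protein=protein,
        antibodies=tuple(f"ab{i}" for i in range(A)),
        tissues=tuple(f"t{j}" for j in range(T)),
        values=values,
    )
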