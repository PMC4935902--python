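"""Named fixture networks.

The catalog holds small reference networks shipped as ``.nel`` files in the
package data directory.  Their topologies are reconstructions built to
satisfy a battery of published structural facts (which convergent and
superconvergent sets exist, which nodes are semi/equivalent, what the
reduction pipeline produces, which distances hold); the test suite's fixture
self-test asserts every one of those facts, so the reconstructions are
checked rather than trusted.
"""

from __future__ import annotations

from importlib import resources

from .errors import PhyloNetworkError
from .io import parse_edgelist
from .network import PhyloNetwork

FIXTURE_NAMES = (
    "fig1_N1",
    "fig1_N2",
    "fig2_N",
    "fig2_N0",
    "fig2_N1",
    "fig2_N2",
    "fig3_reduced",
    "fig4_N1",
    "fig4_N2",
)


class UnknownFixtureError(PhyloNetworkError):
    pass


def load_fixture(name: str) -> PhyloNetwork:
    """Load a catalog network by name (see :data:`FIXTURE_NAMES`)."""
    if name not in FIXTURE_NAMES:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}"
        )
    text = resources.files("phylonetdist.data").joinpath(f"{name}.nel").read_text("utf-8")
    return parse_edgelist(text, strict=True)


def fixture_names() -> tuple[str, ...]:
    return FIXTURE_NAMES
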