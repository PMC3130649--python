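import warnings

import pytest

from yplex import build_tree, load_packaged_panel
from yplex.panel import DyeMap, Marker, MarkerStatus, Panel
from yplex.phylogeny import build_packaged_tree


@pytest.fixture(scope="session")
def panel():
    return load_packaged_panel()


@pytest.fixture(scope="session")
def tree(panel):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # compound-haplogroup skeleton overrides
        return build_packaged_tree(panel)


def make_marker(name, haplogroup, anc="A", der="G", rate=95.0, **kwargs):
    return Marker(
        name=name,
        haplogroup=haplogroup,
        ancestral_allele=anc,
        derived_allele=der,
        published_call_rate=rate,
        **kwargs,
    )


def toy_panel(labels_by_marker: dict[str, str]) -> Panel:
    """One active substitution assay per (marker -> haplogroup label) entry."""
    return Panel([make_marker(m, h) for m, h in labels_by_marker.items()])


def toy_tree(labels_by_marker: dict[str, str], skeleton=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_tree(toy_panel(labels_by_marker), skeleton or {})


@pytest.fixture
def nested_toy():
    """Three-branch toy: A with child A1, sibling B, all marker-defined."""
    markers = {"m_a": "A", "m_a1": "A1", "m_b": "B"}
    return toy_panel(markers), toy_tree(markers)
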