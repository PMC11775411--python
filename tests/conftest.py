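"""Shared fixtures: reconstructed diet fixtures and a hand-built toy
count/hit table exercising every branch of the filter chain."""

from __future__ import annotations

import pandas as pd
import pytest

from scatscape import synthetic as synth
from scatscape.filters import CountTable


@pytest.fixture(scope="session")
def leopard():
    """(DietTruth, presence) reconstructed from the leopard diet table."""
    return synth.fixture_from_tables("leopard", seed=11)


@pytest.fixture(scope="session")
def leopardcat():
    return synth.fixture_from_tables("leopardcat", seed=13)


# --- toy filter-chain table -------------------------------------------------
#
# Control max is 7 reads -> threshold T = 7, so otu_B (<=7 everywhere)
# vanishes. otu_C resolves only to family, otu_D is an arthropod: both
# dropped. In s1, otu_E sits at exactly 1% relative abundance (100/10000)
# -> excluded by the strict >1% rule. Surviving taxa: Bos taurus
# (3 scats) and Lepus nigricollis (2 scats) -> 2 taxa, 5 presences.

TOY_COUNTS = pd.DataFrame(
    {
        "otu_A": [9900, 4950, 980, 0],
        "otu_B": [5, 7, 3, 7],
        "otu_C": [50, 100, 0, 0],
        "otu_D": [80, 200, 0, 0],
        "otu_E": [100, 0, 0, 0],
        "otu_F": [0, 51, 20, 0],
    },
    index=pd.Index(["s1", "s2", "s3", "NEG"], name="sample"),
)

_BOS = "Animalia;Chordata;Mammalia;Artiodactyla;Bovidae;Bos;Bos taurus"
_CAPRA = "Animalia;Chordata;Mammalia;Artiodactyla;Bovidae;Capra;Capra hircus"
_MUS = "Animalia;Chordata;Mammalia;Rodentia;Muridae;Mus;Mus musculus"
_RATTUS = "Animalia;Chordata;Mammalia;Rodentia;Muridae;Rattus;Rattus rattus"
_MOTH = "Animalia;Arthropoda;Insecta;Lepidoptera;Erebidae;Arctia;Arctia caja"
_LEPUS = ("Animalia;Chordata;Mammalia;Lagomorpha;Leporidae;Lepus;"
          "Lepus nigricollis")

TOY_EXPECTED_TAXA = {"Bos taurus": 3, "Lepus nigricollis": 2}


def _hits(otu, lineages, pident=98.5, qcovs=95.0):
    return [{"otu_id": otu, "lineage": ln, "pident": pident, "qcovs": qcovs}
            for ln in lineages]


@pytest.fixture(scope="session")
def toy_table():
    meta = pd.DataFrame(
        {"predator": ["Panthera pardus"] * 3 + [""],
         "is_control": [False, False, False, True]},
        index=TOY_COUNTS.index)
    return CountTable(TOY_COUNTS.copy(), meta)


@pytest.fixture(scope="session")
def toy_hits():
    rows = []
    rows += _hits("otu_A", [_BOS] * 10)  # clean species consensus
    rows += _hits("otu_B", [_CAPRA] * 10)
    # 5 Mus + 5 Rattus: species 50% < 51%, genus 50% < 51%, family 100%
    rows += _hits("otu_C", [_MUS] * 5 + [_RATTUS] * 5)
    rows += _hits("otu_D", [_MOTH] * 10)  # non-vertebrate
    rows += _hits("otu_E", [_CAPRA] * 10)
    rows += _hits("otu_F", [_LEPUS] * 10)
    return pd.DataFrame(rows)
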