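"""Shared fixtures: tiny variant tables encoding the worked examples."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sibshare.filters import ANNOTATION_COLUMNS


def make_variant(**overrides) -> dict:
    """One annotated-variant row with sensible defaults."""
    row = {
        "chrom": "chr1",
        "pos": 1000,
        "ref": "A",
        "alt": "T",
        "gene": "GENE1",
        "func_class": "missense",
        "genotype": "het",
        "carrier_count": 3,
        "n_sibs_tested": 3,
        "af_evs": np.nan,
        "af_hapmap": np.nan,
        "af_1000g": np.nan,
        "af_exac": np.nan,
        "af_gonl": np.nan,
        "af_internal": 0.05,
        "polyphen": np.nan,
        "grantham": np.nan,
        "cadd": 10.0,
    }
    row.update(overrides)
    return row


def variant_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


@pytest.fixture
def sibling_ptv_table() -> pd.DataFrame:
    """Six genes, each with a het PTV plus a het second hit, mirroring a
    sibship screen: only the PDIA2 pair has all members below 2%."""
    pos = iter(range(1000, 100000, 1000))
    rows = [
        # PDIA2: stop-gain absent from GoNL + missense at 1.3% -> prioritized
        make_variant(gene="PDIA2", func_class="stop-gained", pos=next(pos), af_gonl=0.0),
        make_variant(gene="PDIA2", func_class="missense", pos=next(pos), af_gonl=0.013),
        # TLR5: both at 6.5%
        make_variant(gene="TLR5", func_class="stop-gained", pos=next(pos), af_gonl=0.065),
        make_variant(gene="TLR5", func_class="missense", pos=next(pos), af_gonl=0.065),
        # TRPM1: 4.9% / 4.7%
        make_variant(gene="TRPM1", func_class="stop-gained", pos=next(pos), af_gonl=0.049),
        make_variant(gene="TRPM1", func_class="missense", pos=next(pos), af_gonl=0.047),
        # UNC93A: canonical splice at 3.3% / missense 0.7%
        make_variant(gene="UNC93A", func_class="canonical-splice", pos=next(pos), af_gonl=0.033),
        make_variant(gene="UNC93A", func_class="missense", pos=next(pos), af_gonl=0.007),
        # PLXNB3: splice 0% / missense 6.0%
        make_variant(gene="PLXNB3", func_class="canonical-splice", pos=next(pos), af_gonl=0.0),
        make_variant(gene="PLXNB3", func_class="missense", pos=next(pos), af_gonl=0.060),
        # CCHCR1: stop-gain and two missense, all 9.6%
        make_variant(gene="CCHCR1", func_class="stop-gained", pos=next(pos), af_gonl=0.096),
        make_variant(gene="CCHCR1", func_class="missense", pos=next(pos), af_gonl=0.096),
        make_variant(gene="CCHCR1", func_class="missense", pos=next(pos), af_gonl=0.096),
    ]
    return variant_table(rows)


@pytest.fixture
def panel_table() -> pd.DataFrame:
    """Known-gene findings: the CHEK2 frameshift at 1%, a too-common
    high-risk PTV, a rare high-CADD BRCA2 missense, and controls."""
    rows = [
        # CHEK2 c.1100delC-style frameshift at 1% (moderate tier, 2% cut-off)
        make_variant(gene="CHEK2", func_class="frameshift", pos=1100, af_exac=0.01, cadd=25.0),
        # high-risk-gene PTV at 0.5% exceeds the 0.1% tier cut-off
        make_variant(gene="BRCA1", func_class="stop-gained", pos=2000, af_exac=0.005),
        # rare BRCA2 missense with CADD 35
        make_variant(gene="BRCA2", func_class="missense", pos=3000, af_exac=0.0001, cadd=35.0),
        # rare missense in a level-3 gene with low CADD: dropped
        make_variant(gene="BARD1", func_class="missense", pos=4000, af_exac=0.0001, cadd=5.0),
        # rare missense in a level-2 gene with low CADD: kept via level rule
        make_variant(gene="ATM", func_class="missense", pos=5000, af_exac=0.017, cadd=5.0),
        # common missense in panel gene: dropped
        make_variant(gene="CHEK2", func_class="missense", pos=6000, af_exac=0.15, cadd=30.0),
        # variant outside the panel: ignored
        make_variant(gene="NOTAPANELGENE", func_class="stop-gained", pos=7000, af_exac=0.0),
    ]
    return variant_table(rows)
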