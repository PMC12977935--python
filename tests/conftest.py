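import pytest

from dmckit.seqio import Alignment, QueryList, assign_taxa
from dmckit.search import SearchParams
from dmckit.synth import SynthSpec, generate_training_alignment


def make_alignment(rows: dict[str, str], queries: list[str] | None = None) -> Alignment:
    """Build a small assigned alignment from an id → residues mapping."""
    aln = Alignment(ids=list(rows), seqs=list(rows.values()))
    if queries:
        aln = assign_taxa(aln, QueryList(tuple(queries)))
    return aln


@pytest.fixture
def toy_aln() -> Alignment:
    """Two 2-sequence query taxa plus background, 8 columns.

    Taxon Qa is fixed A at column 1 and T at column 3 (absent from all
    background at those columns); taxon Qb is fixed G at column 2.
    """
    return make_alignment(
        {
            "Qa_001": "ACTGACGT",
            "Qa_002": "ACTGACGT",
            "Qb_001": "CGAGACGT",
            "Qb_002": "CGAGACGA",
            "Bg_001": "CCAGACGT",
            "Bg_002": "GCCGACGT",
            "Bg_003": "TCGGATGT",
        },
        queries=["Qa", "Qb"],
    )


@pytest.fixture
def planted_library():
    """Zero-noise synthetic library: diagnosable signal known exactly."""
    spec = SynthSpec(
        n_species=6,
        seqs_per_species=4,
        n_sites=60,
        planted_sites_per_species=2,
        intraspecific_rate=0.0,
        missing_rate=0.0,
        gap_rate=0.0,
        background_divergence=0.2,
        seed=11,
    )
    return generate_training_alignment(spec)


@pytest.fixture
def fast_params() -> SearchParams:
    return SearchParams(n_iter=1500, seed=7, ref_strength=1.0)


@pytest.fixture
def long_params() -> SearchParams:
    """Recommended-practice settings: long DMCs resist chance window hits."""
    return SearchParams(n_iter=1500, min_len=10, seed=7, ref_strength=0.33)
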