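import pytest

from tatascan import GeneAnnotation, PromoterSequence

# the published worked-example promoter contexts (ancestral allele)
CRP_SEQ = "TGCTTTGGATATAAATCCAGG"
SER_SEQ = "GAGTGCAGGTCGCTTTAAGAA"

# printed Kd +/- SE (nM): (ancestral, minor...) per promoter
CRP_KD = [("norm", 2.26, 0.23), ("rs1660782480", 7.64, 0.76), ("rs1660782424", 6.19, 0.62)]
SER_KD = [("norm", 10.21, 0.92), ("rs541151948:A", 7.27, 0.51), ("rs541151948:T", 8.53, 0.77)]


@pytest.fixture
def crp_promoter():
    return PromoterSequence(gene_symbol="CRP", transcript_id="CRP-201", sequence=CRP_SEQ)


@pytest.fixture
def ser_promoter():
    return PromoterSequence(
        gene_symbol="SERPINF1", transcript_id="SERPINF1-205", sequence=SER_SEQ
    )


@pytest.fixture
def hub_annotations():
    """Health-effect annotation for the two worked-example genes: lower
    C-reactive protein relieves all three processes; excess serpin F1
    worsens atherogenesis and atheroprotection but goes with mild
    atherosclerosis."""
    relief_all = {p: "relief" for p in ("atherogenesis", "atherosclerosis", "atheroprotection")}
    worsen_all = {p: "worsen" for p in relief_all}
    return {
        "CRP": GeneAnnotation(
            gene_symbol="CRP",
            membership=frozenset(relief_all),
            pai=4,
            effect_under=relief_all,
            effect_over=worsen_all,
        ),
        "SERPINF1": GeneAnnotation(
            gene_symbol="SERPINF1",
            membership=frozenset(relief_all),
            pai=3,
            effect_under={
                "atherogenesis": "relief",
                "atherosclerosis": "worsen",
                "atheroprotection": "relief",
            },
            effect_over={
                "atherogenesis": "worsen",
                "atherosclerosis": "relief",
                "atheroprotection": "worsen",
            },
        ),
    }
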