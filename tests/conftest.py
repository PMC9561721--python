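import pandas as pd
import pytest

from sigportrait import DEGTable, SignedScoreTable


def make_scores(mapping, study_id="study"):
    """SignedScoreTable from a {gene: sign1} dict."""
    return SignedScoreTable(study_id, pd.Series(mapping, dtype=float))


def make_deg(rows, study_id="study"):
    """DEGTable from (gene, p, direction) tuples."""
    frame = pd.DataFrame(rows, columns=["gene_symbol", "p_value", "direction_value"])
    return DEGTable(study_id, frame)


@pytest.fixture
def geo2r_file(tmp_path):
    """A small GEO2R-style TSV export."""
    path = tmp_path / "GSE000001.tsv"
    path.write_text(
        "ID\tGene.symbol\tP.Value\tlogFC\n"
        "1007_s_at\tGFAP\t0.001\t1.5\n"
        "1053_at\tBDNF\t0.01\t-0.8\n"
        "117_at\tITPKB\t0.0002\t2.1\n"
    )
    return path


@pytest.fixture
def eight_gene_pair():
    """The 8-gene toy pair: up1={G1,G2}, down1={G3,G4}, up2={G3,G5}, down2={G1,G6}."""
    sig1 = make_scores(
        {"G1": 5.0, "G2": 4.0, "G3": -5.0, "G4": -4.0,
         "G5": 0.0, "G6": 0.0, "G7": 0.0, "G8": 0.0},
        study_id="sig1",
    )
    sig2 = make_scores(
        {"G3": 6.0, "G5": 3.0, "G1": -6.0, "G6": -3.0,
         "G2": 0.0, "G4": 0.0, "G7": 0.0, "G8": 0.0},
        study_id="sig2",
    )
    return sig1, sig2
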