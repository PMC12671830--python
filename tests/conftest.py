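import numpy as np
import pytest

from tnfvigil.curation import AGENTS
from tnfvigil.synthetic import SyntheticConfig


@pytest.fixture
def tiny_quarter_dir(tmp_path):
    """Hand-written quarter: 3 DEMO, 4 DRUG (one malformed), 5 REAC rows."""
    q = tmp_path / "2012Q3"
    q.mkdir()
    (q / "DEMO12Q3.txt").write_text(
        "PRIMARYID$CASEID$FDA_DT$EVENT_DT$AGE$AGE_COD$SEX$OCCP_COD$REPORTER_COUNTRY\n"
        "1001$500$20120701$20120615$12$YR$F$MD$US\n"
        "1002$501$20120702$$6$MON$M$CN$US\n"
        "1003$502$20120815$201206$17.5$YR$UNK$OT$GB\n")
    (q / "DRUG12Q3.txt").write_text(
        "PRIMARYID$CASEID$DRUG_SEQ$ROLE_COD$DRUGNAME$PROD_AI\n"
        "1001$500$1$PS$HUMIRA$ADALIMUMAB\n"
        "1001$500$2$C$ASPIRIN$\n"
        "1002$501$1$PS$REMICADE 100MG$INFLIXIMAB\n"
        "1003$502$1$PS$ENBREL$ETANERCEPT\n"
        "1003$502$2$XX$MYSTERY$\n")  # malformed role code
    (q / "REAC12Q3.txt").write_text(
        "PRIMARYID$CASEID$PT\n"
        "1001$500$Pyrexia\n"
        "1001$500$Headache\n"
        "1002$501$Injection site pain\n"
        "1003$502$Uveitis\n"
        "1003$502$Pyrexia\n")
    (q / "OUTC12Q3.txt").write_text(
        "PRIMARYID$CASEID$OUTC_COD\n"
        "1001$500$HO\n"
        "1001$500$LT\n")
    (q / "THER12Q3.txt").write_text(
        "PRIMARYID$CASEID$DSG_DRUG_SEQ$START_DT$END_DT\n"
        "1001$500$1$20120601$\n")
    (q / "INDI12Q3.txt").write_text(
        "PRIMARYID$CASEID$INDI_DRUG_SEQ$INDI_PT\n"
        "1001$500$1$Crohn's disease\n")
    (q / "DELETED12Q3.txt").write_text("")
    return q


@pytest.fixture
def small_config():
    """Small but structurally complete generator configuration."""
    return SyntheticConfig(
        n_cases={a: 120 for a in AGENTS},
        planted_associations={
            ("infliximab", "Clostridium difficile infection"): 10.0},
        seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
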