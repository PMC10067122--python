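import textwrap

import pytest

from icivigil import DrugDictionary, PTCatalog, default_config, generate_reports


@pytest.fixture(scope="session")
def dictionary():
    return DrugDictionary.default()


@pytest.fixture(scope="session")
def catalog():
    return PTCatalog.default()


@pytest.fixture
def tiny_quarter(tmp_path):
    """Hand-written three-case quarter: one revision pair + one clean case."""

    def write(name, text):
        p = tmp_path / name
        p.write_text(textwrap.dedent(text).lstrip())
        return p

    paths = {
        "demo": write(
            "demo2020q1.txt",
            """
            primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$occr_country
            1001$100$20200110$20200105$7$DEC$M$US
            1002$100$20200210$20200105$7$DEC$M$US
            2001$200$20200115$20200210$65$YR$F$JP
            3001$300$20200120$$30$YR$$FR
            """,
        ),
        "drug": write(
            "drug2020q1.txt",
            """
            primaryid$caseid$drug_seq$role_cod$drugname
            1001$100$1$PS$OPDIVO
            1002$100$1$PS$OPDIVO
            2001$200$1$PS$KEYTRUDA 200MG
            2001$200$2$C$ASPIRIN
            3001$300$1$SS$YERVOY
            9999$999$1$PS$GHOST
            """,
        ),
        "reac": write(
            "reac2020q1.txt",
            """
            primaryid$caseid$pt
            1001$100$Atrial fibrillation
            1002$100$Atrial fibrillation
            1002$100$Cardiac arrest
            2001$200$Nausea
            3001$300$Atrial flutter
            """,
        ),
        "outc": write(
            "outc2020q1.txt",
            """
            primaryid$caseid$outc_cod
            1002$100$DE
            1002$100$HO
            2001$200$HO
            """,
        ),
        "ther": write(
            "ther2020q1.txt",
            """
            primaryid$caseid$dsg_drug_seq$start_dt$end_dt
            1002$100$1$20200101$
            2001$200$1$202001$
            """,
        ),
    }
    return paths


@pytest.fixture(scope="session")
def small_db():
    """A 3000-case synthetic database with the default planted multipliers."""
    cfg = default_config(n_reports=3000)
    return generate_reports(cfg, seed=42)
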