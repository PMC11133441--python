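import pytest

from faers_dispro.faers_io import DemoRecord, DrugRecord, ReactionRecord
from faers_dispro.synthetic_data import SyntheticConfig, generate


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="latin-1")
    return path


@pytest.fixture
def demo_file(tmp_path):
    """A small DEMO table exercising missing fields and unit codes."""
    return write_lines(
        tmp_path / "DEMO.txt",
        [
            "primaryid$caseid$fda_dt$sex$age$age_cod$wt$wt_cod$occp_cod$reporter_country",
            "1001$500$20210101$M$65$YR$80$KG$MD$US",
            "1002$501$20210215$$$$$$CN$CA",
        ],
    )


@pytest.fixture
def small_tables():
    """A deterministic small synthetic dataset (500 cases)."""
    return generate(SyntheticConfig(n_cases=500, seed=42))


def make_demo(primary_id="1", case_id="1", fda_dt=20210101, **kwargs):
    return DemoRecord(primary_id=primary_id, case_id=case_id, fda_dt=fda_dt, **kwargs)


def make_drug(primary_id="1", drug_seq=1, role_code="PS", drug_name="SELINEXOR", **kwargs):
    return DrugRecord(
        primary_id=primary_id, drug_seq=drug_seq, role_code=role_code, drug_name=drug_name, **kwargs
    )


def make_reac(primary_id="1", pt="Nausea"):
    return ReactionRecord(primary_id=primary_id, pt=pt)
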