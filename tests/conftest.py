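import pytest
from hypothesis import settings

from pvsignal.event_dictionary import example_dictionary
from pvsignal.faers_io import DrugEntry, PartialDate, SafetyReport, classify_route, parse_partial_date

settings.register_profile("suite", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("suite")


def make_drug(name="AVASTIN", ingredient="BEVACIZUMAB", role="PS",
              route="INTRAVENOUS", seq="1"):
    return DrugEntry(
        drug_seq=seq, verbatim_name=name.upper(),
        normalized_ingredient=ingredient.upper(), role_code=role,
        route=route, route_class=classify_route(route),
    )


def make_report(primaryid="1", caseid=None, fda="20230601", event="20230501",
                start="20230401", sex="M", age=60.0, reporter="physician",
                country="US", outcomes=(), drugs=None, pts=("NAUSEA",),
                indications=()):
    return SafetyReport(
        primaryid=primaryid,
        caseid=caseid if caseid is not None else primaryid,
        fda_date=parse_partial_date(fda),
        event_date=parse_partial_date(event),
        sex=sex,
        age_years=age,
        reporter_qualification=reporter,
        country=country,
        outcome_codes=frozenset(outcomes),
        drugs=list(drugs) if drugs is not None else [make_drug()],
        reaction_pts=frozenset(p.upper() for p in pts),
        indications=list(indications),
        therapy_start=parse_partial_date(start),
    )


@pytest.fixture(scope="session")
def dictionary():
    return example_dictionary()
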