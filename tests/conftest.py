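import pandas as pd
import pytest

from toxflux.model import MetabolicModel, Metabolite, Reaction


def build_chain_model(ex_ub: float = 10.0, r1_ub: float = 5.0, growth_ub: float = 1000.0):
    """EX_A (uptake capacity ex_ub) -> R1: A->B (ub r1_ub) -> GROWTH: B drain.

    The optimal growth is min(ex_ub, r1_ub, growth_ub).
    """
    m = MetabolicModel(name="chain", version="1")
    m.add_metabolite(Metabolite(id="A", compartment="c"))
    m.add_metabolite(Metabolite(id="B", compartment="c"))
    m.add_reaction(
        Reaction(id="EX_A", stoichiometry={"A": -1.0}, lower_bound=-ex_ub, upper_bound=0.0)
    )
    m.add_reaction(
        Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=r1_ub)
    )
    m.add_reaction(
        Reaction(id="GROWTH", stoichiometry={"B": -1.0}, lower_bound=0.0, upper_bound=growth_ub)
    )
    m.objective_reaction_id = "GROWTH"
    return m


@pytest.fixture
def chain_model():
    return build_chain_model()


@pytest.fixture
def parallel_branch_model():
    """Demand of 5 routed through two equivalent parallel branches."""
    m = MetabolicModel(name="parallel", version="1")
    for mid in ("A", "B"):
        m.add_metabolite(Metabolite(id=mid, compartment="c"))
    m.add_reaction(
        Reaction(id="EX_A", stoichiometry={"A": -1.0}, lower_bound=-5.0, upper_bound=0.0)
    )
    for b in ("P1", "P2"):
        m.add_reaction(
            Reaction(id=b, stoichiometry={"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=1000.0)
        )
    m.add_reaction(
        Reaction(id="GROWTH", stoichiometry={"B": -1.0}, lower_bound=0.0, upper_bound=1000.0)
    )
    m.objective_reaction_id = "GROWTH"
    return m


def make_feature_table(values: dict[str, list[float]], n_control: int, platform: str = "ESI"):
    """FeatureTable from feature -> row values; first n_control samples are control."""
    from toxflux.metabolomics import FeatureTable

    n = len(next(iter(values.values())))
    samples = [f"s{i + 1}" for i in range(n)]
    group_of = {s: ("control" if i < n_control else "treated") for i, s in enumerate(samples)}
    df = pd.DataFrame(values, index=samples).T.astype(float)
    return FeatureTable(intensities=df, group_of=group_of, platform=platform)
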