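import cobra
import pytest

from gemtide.synth import make_toy_model


@pytest.fixture(scope="session")
def toy():
    """The deterministic toy network and its task catalogue (read-only)."""
    model, tasks = make_toy_model()
    return model, tasks


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_tasks(toy):
    return toy[1]


def _met(mid, compartment):
    return cobra.Metabolite(mid, compartment=compartment)


def build_chain_model(ex_lb=-10.0):
    """EX_A -> transport -> A->B -> B->ATP -> ATP demand, objective = demand."""
    model = cobra.Model("chain")
    a_e, a_c, b_c, atp_c = _met("A_e", "e"), _met("A_c", "c"), _met("B_c", "c"), _met("ATP_c", "c")
    rxns = []
    for rid, stoich, bounds in [
        ("EX_A_e", {a_e: -1}, (ex_lb, 1000)),
        ("At", {a_e: -1, a_c: 1}, (0, 1000)),
        ("AB", {a_c: -1, b_c: 1}, (0, 1000)),
        ("BATP", {b_c: -1, atp_c: 1}, (0, 1000)),
        ("DM_ATP", {atp_c: -1}, (0, 1000)),
    ]:
        rxn = cobra.Reaction(rid, lower_bound=bounds[0], upper_bound=bounds[1])
        rxn.add_metabolites(stoich)
        rxns.append(rxn)
    model.add_reactions(rxns)
    model.objective = "DM_ATP"
    return model


def build_parallel_model():
    """Two routes from A to ATP: one with 2 internal steps, one with 3."""
    model = cobra.Model("parallel")
    mets = {m: _met(m, "c" if m.endswith("_c") else "e")
            for m in ("A_e", "A_c", "X_c", "Y1_c", "Y2_c", "ATP_c")}
    spec = [
        ("EX_A_e", {"A_e": -1}, (-10, 1000)),
        ("At", {"A_e": -1, "A_c": 1}, (0, 1000)),
        # short route (2 steps)
        ("AX", {"A_c": -1, "X_c": 1}, (0, 1000)),
        ("XATP", {"X_c": -1, "ATP_c": 1}, (0, 1000)),
        # long route (3 steps)
        ("AY1", {"A_c": -1, "Y1_c": 1}, (0, 1000)),
        ("Y1Y2", {"Y1_c": -1, "Y2_c": 1}, (0, 1000)),
        ("Y2ATP", {"Y2_c": -1, "ATP_c": 1}, (0, 1000)),
        ("DM_ATP", {"ATP_c": -1}, (0, 1000)),
    ]
    rxns = []
    for rid, stoich, bounds in spec:
        rxn = cobra.Reaction(rid, lower_bound=bounds[0], upper_bound=bounds[1])
        rxn.add_metabolites({mets[k]: v for k, v in stoich.items()})
        rxns.append(rxn)
    model.add_reactions(rxns)
    model.objective = "DM_ATP"
    return model
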