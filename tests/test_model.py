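"""Cluster PC1 surrogates, stepwise partial-F selection, reconstruction."""

import numpy as np
import pandas as pd
import pytest

import modrsm as m
from modrsm.model import ledger_to_json
from modrsm.terms import SQUARED, TIMES, canonical_term

from conftest import make_response_matrix


# ------------------------------------------------------------ cluster_pc1 ----

def test_single_member_cluster_degenerates(scaled42):
    pc = m.cluster_pc1(scaled42, ["Ethyl acetate"], cluster_id=1)
    assert pc.loadings_pc1.tolist() == [1.0]
    assert pc.explained.tolist() == [100.0]
    assert np.allclose(pc.scores_pc1, scaled42.data["Ethyl acetate"])


def test_two_member_cluster_loading_magnitudes(scaled42):
    """Any two standardized variables load PC1 at exactly +-1/sqrt(2)."""
    pc = m.cluster_pc1(scaled42, ["R100", "MFR"], cluster_id=2)
    assert np.allclose(np.abs(pc.loadings_pc1), 1 / np.sqrt(2), atol=1e-10)
    assert round(abs(pc.loadings_pc1[0]), 4) == 0.7071


def test_two_member_explained_closed_form(rng):
    """PC1 of a standardized pair explains 100*(1+|r|)/2 percent."""
    for _ in range(5):
        a = rng.normal(size=31)
        b = rng.uniform(-1, 1) * a + rng.normal(size=31)
        X = m.autoscale(make_response_matrix(np.column_stack([a, b]), ["a", "b"]))
        r = np.corrcoef(X.values.T)[0, 1]
        pc = m.cluster_pc1(X, ["a", "b"])
        assert pc.explained[0] == pytest.approx(100 * (1 + abs(r)) / 2, abs=1e-8)


def test_cluster_pc1_input_checks(scaled42):
    with pytest.raises(ValueError):
        m.cluster_pc1(scaled42, [])
    with pytest.raises(KeyError):
        m.cluster_pc1(scaled42, ["nope"])


# ------------------------------------------------------------- build_terms ----

def test_term_expansion_order(design31):
    ts = m.build_terms(design31)
    T, S = TIMES, SQUARED
    assert ts.labels == [
        "S", "N", "T", "I",
        f"S{T}N", f"S{T}T", f"S{T}I", f"N{T}T", f"N{T}I", f"T{T}I",
        f"S{S}", f"N{S}", f"T{S}", f"I{S}",
    ]
    assert set(np.unique(ts.values[f"S{S}"])) == {0.0, 1.0}
    prod = ts.values["S"] * ts.values["N"]
    assert np.allclose(ts.values[f"S{T}N"], prod)


def test_two_factor_design_has_five_terms():
    d = m.generate_ccd(k=2, alpha=1, n_center=3, seed=0)
    assert len(m.build_terms(d).labels) == 5


def test_term_label_canonicalization(design31):
    names = design31.factor_names
    assert canonical_term("N*T", names) == f"N{TIMES}T"
    assert canonical_term("T x N", names) == f"N{TIMES}T"
    assert canonical_term("S^2", names) == f"S{SQUARED}"
    assert canonical_term("S2", names) == f"S{SQUARED}"


# ------------------------------------------------------------ stepwise_fit ----

def test_exact_single_term_recovered(design31):
    ts = m.build_terms(design31).standardize()
    y = ts.values["T"].to_numpy().copy()
    rep = m.stepwise_fit(y, ts)
    assert rep.selected == ["T"]
    assert rep.r_squared == pytest.approx(1.0, abs=1e-10)
    assert rep.beta[0] == pytest.approx(1.0, abs=1e-10)


def test_r_squared_nondecreasing_along_adds(design31, rng):
    ts = m.build_terms(design31).standardize()
    cols = ts.values.to_numpy()
    y = cols @ rng.normal(size=cols.shape[1]) + rng.normal(size=31)
    rep = m.stepwise_fit(y, ts)
    added, r2s = [], []
    for ev in rep.selection_trace:
        if ev["action"] == "add":
            added.append(ev["term"])
            X = np.column_stack([np.ones(31), ts.values[added].to_numpy()])
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            r2s.append(1 - resid @ resid / ((y - y.mean()) @ (y - y.mean())))
    assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))


def test_partial_f_equals_squared_t():
    """For single-term additions, partial F == t^2 of the new coefficient."""
    import statsmodels.api as sm
    from modrsm.model import _partial_f, _rss

    rng = np.random.default_rng(5)
    for _ in range(1000):
        n = rng.integers(10, 25)
        p = rng.integers(1, 4)
        X = rng.normal(size=(n, p + 1))
        y = rng.normal(size=n)
        rss_red = _rss(y, X[:, :p])
        rss_full = _rss(y, X)
        F, _ = _partial_f(rss_red, rss_full, n, p + 2)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        t = fit.tvalues[-1]
        assert abs(F - t**2) < 1e-8


def brute_force_stepwise(y, cols_df, labels, alpha=0.05):
    """Independent greedy re-implementation: full re-fit at every scan."""
    import statsmodels.api as sm

    n = len(y)
    selected = []
    for _ in range(100):
        changed = False
        # entry: smallest p among candidates, earlier label on ties
        best_p, best_lab = None, None
        for lab in labels:
            if lab in selected or n - (len(selected) + 2) < 2:
                continue
            X = sm.add_constant(cols_df[selected + [lab]])
            fit = sm.OLS(y, X).fit()
            pval = fit.pvalues[lab]
            if pval < alpha and (
                best_p is None
                or (pval, labels.index(lab)) < (best_p, labels.index(best_lab))
            ):
                best_p, best_lab = pval, lab
        if best_lab is not None:
            selected.append(best_lab)
            changed = True
        # removal: largest p above alpha
        if selected:
            X = sm.add_constant(cols_df[selected])
            fit = sm.OLS(y, X).fit()
            pv = fit.pvalues[selected]
            worst = pv.idxmax()
            if pv[worst] > alpha:
                selected.remove(worst)
                changed = True
        if not changed:
            break
    return selected


@pytest.mark.parametrize("seed", range(12))
def test_stepwise_path_matches_brute_force_oracle(seed):
    """The greedy path agrees exactly with an independent re-implementation."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(12, 21))
    p = int(rng.integers(3, 8))
    labels = [f"t{i}" for i in range(p)]
    cols = rng.normal(size=(n, p))
    true_beta = np.where(rng.random(p) < 0.5, 0.0, rng.normal(0, 1.5, p))
    y = cols @ true_beta + rng.normal(size=n)
    values = pd.DataFrame(cols, columns=labels)
    ts = m.TermSet(labels=labels, values=values).standardize()
    rep = m.stepwise_fit(y, ts)
    oracle = brute_force_stepwise(y, ts.values, labels)
    assert rep.selected == oracle


def test_pure_noise_empty_model_rate_matches_monte_carlo_oracle():
    """With y independent of all terms the empty-model rate matches an
    independent Monte-Carlo run of the same greedy rule (+-3 points)."""
    rng = np.random.default_rng(2026)
    labels = [f"t{i}" for i in range(5)]
    n = 20

    def empty_rate_impl(reps):
        empty = 0
        for _ in range(reps):
            cols = rng.normal(size=(n, 5))
            ts = m.TermSet(labels=labels, values=pd.DataFrame(cols, columns=labels)).standardize()
            y = rng.normal(size=n)
            empty += not m.stepwise_fit(y, ts).selected
        return empty / reps

    def empty_rate_oracle(reps):
        empty = 0
        for _ in range(reps):
            cols = rng.normal(size=(n, 5))
            values = pd.DataFrame(
                (cols - cols.mean(0)) / cols.std(0, ddof=1), columns=labels
            )
            y = rng.normal(size=n)
            empty += not brute_force_stepwise(y, values, labels)
        return empty / reps

    assert abs(empty_rate_impl(400) - empty_rate_oracle(1500)) < 0.03


def _align_sign(fitted, generating):
    """Sign relating a fitted PC1 direction to the generating loadings."""
    return np.sign(np.dot(fitted, generating))


def test_generating_terms_recovered_across_replicates(design31):
    """Strong generating effects (|beta| >= 0.4) are selected with matching
    signs in >=95% of replicates; spurious terms stay rare (<=10% each)."""
    module = m.default_truth(0.05)[3]  # primary fermentation products
    ts = m.build_terms(design31).standardize()
    strong = {t: b for t, b in module.betas.items() if abs(b) >= 0.4}
    n_rep = 200
    hits = {t: 0 for t in strong}
    sign_ok = {t: 0 for t in strong}
    spurious = {t: 0 for t in ts.labels if t not in module.betas}
    for seed in range(n_rep):
        ds = m.simulate_responses(design31, [module], seed=seed)
        sc = m.autoscale(ds.responses)
        pc = m.cluster_pc1(sc, module.members)
        rep = m.stepwise_fit(pc.scores_pc1, ts)
        flip = _align_sign(pc.loadings_pc1, module.loadings)
        fitted = dict(zip(rep.selected, rep.beta))
        for t, b in strong.items():
            if t in fitted:
                hits[t] += 1
                if np.sign(flip * fitted[t]) == np.sign(b):
                    sign_ok[t] += 1
        for t in rep.selected:
            if t in spurious:
                spurious[t] += 1
    for t in strong:
        assert hits[t] / n_rep >= 0.95, f"{t} selected in only {hits[t]}/{n_rep}"
        assert sign_ok[t] == hits[t]
    for t, c in spurious.items():
        assert c / n_rep <= 0.10, f"spurious {t} entered {c}/{n_rep}"


def test_degrees_of_freedom_guard():
    rng = np.random.default_rng(0)
    n, p = 6, 8
    labels = [f"t{i}" for i in range(p)]
    ts = m.TermSet(labels=labels, values=pd.DataFrame(rng.normal(size=(n, p)), columns=labels)).standardize()
    y = rng.normal(size=n)
    rep = m.stepwise_fit(y, ts)
    # intercept + selected + 1 must always leave >= 2 residual df
    assert len(rep.selected) <= n - 4 + 1
    assert any(ev["action"] == "refuse" for ev in rep.selection_trace) or len(rep.selected) < 3


# ------------------------------------------------------------ reconstruct ----

def test_rank_one_reconstruction_exact(design31):
    mods = [m.default_truth(0.0)[4]]
    ds = m.simulate_responses(design31, mods, seed=8)
    sc = m.autoscale(ds.responses)
    pc = m.cluster_pc1(sc, mods[0].members)
    recon = m.reconstruct(pc, pc.scores_pc1, sc.scaling)
    assert np.max(np.abs(recon.to_numpy() - ds.responses.values)) < 1e-8


def test_zero_scores_reconstruct_to_member_means(design31, dataset42, scaled42):
    members = dataset42.truth[3].members
    pc = m.cluster_pc1(scaled42, members)
    recon = m.reconstruct(pc, np.zeros(31), scaled42.scaling)
    means = dataset42.responses.data[members].mean()
    assert np.allclose(recon.to_numpy(), np.tile(means.to_numpy(), (31, 1)), atol=1e-10)


def test_reconstruction_error_monotone_in_noise(design31):
    """Reconstruction RMSE from model-predicted scores shrinks with sigma."""
    rmses = []
    for sigma in (0.5, 0.1, 0.02):
        vals = []
        for seed in range(50):
            ds = m.simulate_responses(design31, [m.default_truth(sigma)[4]], seed=seed)
            sc = m.autoscale(ds.responses)
            members = ds.truth[0].members
            pc = m.cluster_pc1(sc, members)
            recon = m.reconstruct(pc, pc.scores_pc1, sc.scaling)
            vals.append(
                np.sqrt(np.mean((recon.to_numpy() - ds.responses.values) ** 2))
            )
        rmses.append(np.mean(vals))
    assert rmses[0] > rmses[1] > rmses[2]


def test_reconstruct_requires_scaling(design31, dataset42, scaled42):
    pc = m.cluster_pc1(scaled42, dataset42.truth[3].members)
    partial = scaled42.scaling[["Ethanol"]]
    with pytest.raises(ValueError, match="scaling"):
        m.reconstruct(pc, np.zeros(31), partial)


# -------------------------------------------------------------- summarize ----

def test_summary_ledger_structure(design31, dataset42, scaled42):
    ts = m.build_terms(design31).standardize()
    pcs, reps = [], []
    for cid, mod in enumerate(dataset42.truth, start=1):
        pc = m.cluster_pc1(scaled42, mod.members, cluster_id=cid)
        pcs.append(pc)
        reps.append(m.stepwise_fit(pc.scores_pc1, ts, cluster_id=cid))
    tab = m.summarize(reps, pcs)
    assert sorted(tab.cluster_id.unique()) == [1, 2, 3, 4, 5]
    assert (tab.composition != "").sum() == 18
    assert tab.groupby("cluster_id")["r_squared"].count().tolist() == [1] * 5
    # lossless JSON round trip
    import json

    payload = json.loads(ledger_to_json(reps, pcs))
    assert [b["cluster_id"] for b in payload] == [1, 2, 3, 4, 5]
    for block, rep in zip(payload, reps):
        assert block["selected"] == rep.selected
        assert np.allclose(block["beta"], rep.beta)


def test_summary_with_empty_selection(design31, scaled42):
    ts = m.build_terms(design31).standardize()
    pc = m.cluster_pc1(scaled42, ["Ethyl acetate"], cluster_id=1)
    rng = np.random.default_rng(1)
    rep = m.stepwise_fit(rng.normal(size=31), ts, alpha_enter=1e-9, cluster_id=1)
    assert rep.selected == [] and rep.r_squared == 0.0
    tab = m.summarize([rep], [pc])
    assert len(tab) == 1 and tab.term.iloc[0] == ""
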