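"""Graph-to-graph generative model for property-matched decoys.

The model encodes an active molecule with a gated-graph neural network into
a latent Gaussian, then decodes a new molecule *bond by bond* in a
breadth-first manner from a pool of typed atoms, with every action masked by
basic valency rules so generated molecules are chemically valid by
construction.  Training is a variational autoencoder over molecule pairs
(structurally dissimilar, property-similar): the decoder is teacher-forced
through the construction trace of the partner molecule.

The action cross-entropy is reweighted by the reciprocal frequency of the
local subgraph each action would create::

    L = -fbar * log( p(x_j) f(x_j) / sum_i p(x_i) f(x_i) )

where ``p(x_i)`` is the model probability of permitted action ``x_i``,
``f(x_i)`` the reciprocal frequency of the induced local subgraph across the
training molecules, and ``fbar`` the mean of ``f`` over permitted actions.
With all frequencies equal this reduces exactly to the standard
cross-entropy.  Rare local chemistry is thereby penalised during training,
discouraging subgraphs unseen in the training library.

Total objective: ``L_total = L_recon + lambda_KL * L_KL`` with
``L_recon`` the sum of an atom-type term and the action-sequence term.
"""

from __future__ import annotations

import ast
import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator

from .chem import (Atom, AtomType, AtomVocabulary, Bond, Molecule,
                   check_valence)
from .nn import autodiff as ad
from .nn.autodiff import Adam, Tensor

logger = logging.getLogger(__name__)

_ORDERS = (1, 2, 3)


def kekulized(mol: Molecule) -> Molecule:
    """Copy of ``mol`` with aromatic bonds resolved to alternating 1/2.

    The generator works exclusively on kekulé graphs so that bond orders are
    integral and valence masking is exact.
    """
    rd = Chem.Mol(mol.to_rdkit())
    Chem.Kekulize(rd, clearAromaticFlags=True)
    atoms = [Atom(a.GetSymbol(), a.GetFormalCharge(), False)
             for a in rd.GetAtoms()]
    order_map = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2,
                 Chem.BondType.TRIPLE: 3}
    bonds = [Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                  order_map[b.GetBondType()]) for b in rd.GetBonds()]
    return Molecule(atoms, bonds, mol.name)


# ---------------------------------------------------------------------------
# Subgraph frequency table
# ---------------------------------------------------------------------------

def _environment_key(atom_types, bonds, bond):
    """Canonical radius-1 environment around ``bond``.

    The key records the new bond's order and, for each endpoint, its
    (element, charge) and the sorted orders of all incident bonds — the
    local subgraph the action creates.
    """
    incident = {}
    for b in bonds:
        incident.setdefault(b.i, []).append(b.order)
        incident.setdefault(b.j, []).append(b.order)

    def desc(idx):
        t = atom_types[idx]
        return (t.element, t.charge, tuple(sorted(incident.get(idx, []))))

    return (bond.order, tuple(sorted([desc(bond.i), desc(bond.j)])))


class SubgraphFrequencyTable:
    """Counts of bond-centred local environments over training molecules.

    Reciprocal frequencies use add-one smoothing so the lookup is finite and
    positive for keys never seen in training.
    """

    def __init__(self, counts: dict, total: int):
        self.counts = dict(counts)
        self.total = int(total)

    def count(self, key) -> int:
        return self.counts.get(key, 0) + 1  # smoothed, always >= 1

    def reciprocal_frequency(self, key) -> float:
        """f = smoothed total / smoothed count (>= 1 for seen-often keys)."""
        return (self.total + 1) / self.count(key)

    def to_json(self) -> str:
        return json.dumps({"total": self.total,
                           "counts": {repr(k): v
                                      for k, v in self.counts.items()}})

    @classmethod
    def from_json(cls, text: str) -> "SubgraphFrequencyTable":
        obj = json.loads(text)
        counts = {ast.literal_eval(k): v for k, v in obj["counts"].items()}
        return cls(counts, obj["total"])


def build_frequency_table(mols, environment_radius: int = 1
                          ) -> SubgraphFrequencyTable:
    """Count every bond-centred local environment across ``mols``."""
    if environment_radius != 1:
        raise NotImplementedError("only radius-1 environments are supported")
    counts: dict = {}
    total = 0
    for mol in mols:
        types = [AtomType(a.element, a.charge) for a in mol.atoms]
        for b in mol.bonds:
            key = _environment_key(types, mol.bonds, b)
            counts[key] = counts.get(key, 0) + 1
            total += 1
    return SubgraphFrequencyTable(counts, total)


# ---------------------------------------------------------------------------
# Action distributions and the reweighted loss
# ---------------------------------------------------------------------------

@dataclass
class ActionDistribution:
    """Probabilities and reciprocal-frequency weights over permitted actions."""

    probs: np.ndarray
    freqs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, float)
        self.freqs = np.asarray(self.freqs, float)
        if self.probs.shape != self.freqs.shape:
            raise ValueError("probs and freqs must have equal length")
        if np.any(self.freqs <= 0):
            raise ValueError("frequency weights must be positive")

    @property
    def mean_freq(self) -> float:
        return float(self.freqs.mean())


def reweighted_action_loss(dist: ActionDistribution, chosen: int) -> float:
    """Frequency-reweighted cross-entropy of the chosen action.

    Reduces to ``-log p(x_j)`` when all weights are equal.  A zero model
    probability is clamped with a small epsilon (warned) to keep the loss
    finite.
    """
    p, f = dist.probs, dist.freqs
    pj = p[chosen]
    if pj <= 0:
        warnings.warn("chosen action has zero probability; clamped")
        pj = 1e-12
    ratio = pj * f[chosen] / float(np.dot(p, f))
    return float(-dist.mean_freq * np.log(ratio))


# ---------------------------------------------------------------------------
# Construction traces (teacher forcing)
# ---------------------------------------------------------------------------

def construction_trace(mol: Molecule):
    """Breadth-first bond-by-bond construction of a kekulé molecule.

    Returns ``(atom_order, steps)`` where ``steps`` is a list of
    ``(focus, target, order)`` bond actions interleaved with
    ``(focus, None, 0)`` stop actions.  Atom visit order is canonicalised by
    RDKit ranks so the trace is unique per graph.
    """
    if mol.n_atoms == 0:
        raise ValueError("empty molecule")
    ranks = list(Chem.CanonicalRankAtoms(mol.to_rdkit()))
    start = int(np.argmin(ranks))
    adj: dict[int, list[int]] = {i: [] for i in range(mol.n_atoms)}
    order_of = {}
    for b in mol.bonds:
        adj[b.i].append(b.j)
        adj[b.j].append(b.i)
        order_of[(b.i, b.j)] = order_of[(b.j, b.i)] = b.order
    placed = {start}
    atom_order = [start]
    queue = [start]
    done_bonds = set()
    steps = []
    while queue:
        v = queue[0]
        pending = [u for u in sorted(adj[v], key=lambda u: ranks[u])
                   if (min(v, u), max(v, u)) not in done_bonds]
        if not pending:
            steps.append((v, None, 0))
            queue.pop(0)
            continue
        u = pending[0]
        steps.append((v, u, order_of[(v, u)]))
        done_bonds.add((min(v, u), max(v, u)))
        if u not in placed:
            placed.add(u)
            atom_order.append(u)
            queue.append(u)
    return atom_order, steps


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _init_params(vocab_size, hidden, latent, action_hidden, rng):
    def w(*shape):
        return rng.normal(0.0, 0.1, size=shape)

    p = {
        "embed": w(vocab_size, hidden),
        "z_proj": w(latent, hidden),
        "mu_w": w(hidden, latent), "mu_b": np.zeros(latent),
        "ls_w": w(hidden, latent), "ls_b": np.zeros(latent),
        "gate_w": w(hidden, 1), "gate_b": np.zeros(1),
        "out_w": w(hidden, hidden), "out_b": np.zeros(hidden),
        "act_w1": w(2 * hidden + latent, action_hidden),
        "act_b1": np.zeros(action_hidden),
        "act_w2": w(action_hidden, len(_ORDERS)),
        "act_b2": np.zeros(len(_ORDERS)),
        "stop_w1": w(hidden + latent, action_hidden),
        "stop_b1": np.zeros(action_hidden),
        "stop_w2": w(action_hidden, 1), "stop_b2": np.zeros(1),
        "type_w": w(latent, vocab_size), "type_b": np.zeros(vocab_size),
    }
    for side in ("enc", "dec"):
        for o in range(len(_ORDERS)):
            p[f"{side}_msg_w{o}"] = w(hidden, hidden)
            p[f"{side}_msg_b{o}"] = np.zeros(hidden)
        for gate in ("z", "r", "h"):
            p[f"{side}_gru_w{gate}"] = w(hidden, hidden)
            p[f"{side}_gru_u{gate}"] = w(hidden, hidden)
            p[f"{side}_gru_b{gate}"] = np.zeros(hidden)
    return p


def _adjacency(n, bonds):
    mats = [np.zeros((n, n)) for _ in _ORDERS]
    for b in bonds:
        k = _ORDERS.index(b.order)
        mats[k][b.i, b.j] = mats[k][b.j, b.i] = 1.0
    return mats


def _message_pass(h, adj, params, side, rounds):
    for _ in range(rounds):
        m = 0.0
        for o in range(len(_ORDERS)):
            m = m + (adj[o] @ h) @ params[f"{side}_msg_w{o}"] \
                + params[f"{side}_msg_b{o}"]
        zg = ad.sigmoid(m @ params[f"{side}_gru_wz"]
                        + h @ params[f"{side}_gru_uz"]
                        + params[f"{side}_gru_bz"])
        rg = ad.sigmoid(m @ params[f"{side}_gru_wr"]
                        + h @ params[f"{side}_gru_ur"]
                        + params[f"{side}_gru_br"])
        hh = ad.tanh(m @ params[f"{side}_gru_wh"]
                     + (rg * h) @ params[f"{side}_gru_uh"]
                     + params[f"{side}_gru_bh"])
        h = (1.0 - zg) * h + zg * hh
    return h


class _DecodeState:
    """Mutable bookkeeping for one bond-by-bond construction."""

    def __init__(self, pool_types, vocab):
        self.types = list(pool_types)
        self.vocab = vocab
        self.bonds: list[Bond] = []
        self.placed = [False] * len(self.types)
        self.remaining = [vocab.valence(t) for t in self.types]
        self.queue: list[int] = []

    def place(self, idx):
        self.placed[idx] = True
        self.queue.append(idx)

    def add_bond(self, i, j, order):
        self.bonds.append(Bond(i, j, order))
        self.remaining[i] -= order
        self.remaining[j] -= order

    def bonded(self, i, j):
        return any({b.i, b.j} == {i, j} for b in self.bonds)

    def permitted_actions(self, focus):
        """(target, order) bond actions legal from ``focus``; stop is
        always permitted and handled separately."""
        actions = []
        rep_of_type = {}
        for idx, t in enumerate(self.types):
            if not self.placed[idx] and t not in rep_of_type:
                rep_of_type[t] = idx
        candidates = [i for i in range(len(self.types))
                      if self.placed[i] and i != focus
                      and not self.bonded(focus, i)]
        candidates += sorted(rep_of_type.values())
        for u in candidates:
            for o in _ORDERS:
                if self.remaining[focus] >= o and self.remaining[u] >= o:
                    actions.append((u, o))
        return actions

    def molecule(self, name="") -> Molecule:
        keep = [i for i in range(len(self.types)) if self.placed[i]]
        remap = {old: new for new, old in enumerate(keep)}
        atoms = [Atom(self.types[i].element, self.types[i].charge)
                 for i in keep]
        bonds = [Bond(remap[b.i], remap[b.j], b.order) for b in self.bonds]
        return Molecule(atoms, bonds, name)


class DecoyGenerator(BaseEstimator):
    """Gated-graph VAE that translates actives into candidate decoys.

    scikit-learn estimator conventions: hyperparameters are constructor
    arguments, ``fit`` learns from molecule pairs, fitted state lives in
    trailing-underscore attributes, and generation is exposed as ``sample``.

    Parameters
    ----------
    hidden_size : node-state width of the gated-graph networks.
    latent_size : dimension of the molecule-level latent Gaussian.
    mp_rounds : message-passing rounds per state refresh.
    action_hidden : hidden width of the action/stop scoring MLPs.
    epochs, learning_rate : Adam training schedule.
    lambda_kl : weight of the KL regulariser (linear warm-up over
        ``kl_warmup`` epochs).
    max_heavy_atoms : hard cap on the atom budget at generation time.
    random_state : seed for initialisation and training-time sampling.
    """

    def __init__(self, hidden_size=24, latent_size=8, mp_rounds=2,
                 action_hidden=32, epochs=30, learning_rate=0.01,
                 lambda_kl=1.0, kl_warmup=5, max_heavy_atoms=20,
                 environment_radius=1, random_state=0):
        self.hidden_size = hidden_size
        self.latent_size = latent_size
        self.mp_rounds = mp_rounds
        self.action_hidden = action_hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.lambda_kl = lambda_kl
        self.kl_warmup = kl_warmup
        self.max_heavy_atoms = max_heavy_atoms
        self.environment_radius = environment_radius
        self.random_state = random_state

    # -- encoding ---------------------------------------------------------

    def _type_indices(self, mol: Molecule):
        idx = []
        for a in mol.atoms:
            t = AtomType(a.element, a.charge)
            if t not in self.vocab_:
                raise ValueError(
                    f"atom type {t} not in the model vocabulary")
            idx.append(self.vocab_.index(t))
        return np.array(idx, int)

    def encode(self, mol: Molecule, params=None):
        """Latent Gaussian (mean, scale) for a molecule; deterministic."""
        params = params if params is not None else self.params_
        kek = kekulized(mol)
        tidx = self._type_indices(kek)
        adj = _adjacency(kek.n_atoms, kek.bonds)
        h = params["embed"][tidx]
        h = _message_pass(h, adj, params, "enc", self.mp_rounds)
        gate = ad.sigmoid(h @ params["gate_w"] + params["gate_b"])
        g = (gate * ad.tanh(h @ params["out_w"] + params["out_b"])).sum(axis=0)
        mu = g @ params["mu_w"] + params["mu_b"]
        log_sigma = g @ params["ls_w"] + params["ls_b"]
        return mu, log_sigma

    # -- decoding ---------------------------------------------------------

    def _node_states(self, state: _DecodeState, z, params):
        tidx = np.array([self.vocab_.index(t) for t in state.types], int)
        adj = _adjacency(len(state.types), state.bonds)
        h = params["embed"][tidx] + z.reshape(1, -1) @ params["z_proj"]
        return _message_pass(h, adj, params, "dec", self.mp_rounds)

    def _action_scores(self, state, focus, actions, z, params):
        """Logits over [stop] + bond actions, plus their frequency weights."""
        h = self._node_states(state, z, params)
        zrow = z.reshape(1, -1)
        hf = h[focus:focus + 1]
        stop_in = ad.concat([hf, zrow], axis=1)
        stop_logit = ad.tanh(stop_in @ params["stop_w1"] + params["stop_b1"]) \
            @ params["stop_w2"] + params["stop_b2"]
        logits = [stop_logit.reshape(1)]
        if actions:
            targets = sorted({u for u, _ in actions})
            trow = {u: k for k, u in enumerate(targets)}
            ht = h[np.array(targets, int)]
            n = len(targets)
            inp = ad.concat([_tile(hf, n), ht, _tile(zrow, n)], axis=1)
            per_order = ad.tanh(inp @ params["act_w1"] + params["act_b1"]) \
                @ params["act_w2"] + params["act_b2"]
            for (u, o) in actions:
                logits.append(per_order[trow[u]:trow[u] + 1,
                                        _ORDERS.index(o)].reshape(1))
        bond_freqs = []
        for (u, o) in actions:
            key = _environment_key(state.types,
                                   state.bonds + [Bond(focus, u, o)],
                                   Bond(focus, u, o))
            bond_freqs.append(self.freq_table_.reciprocal_frequency(key))
        # stop has no induced subgraph; the mean weight of the competing
        # bond actions keeps it neutral under the reweighting
        stop_freq = float(np.mean(bond_freqs)) if bond_freqs else 1.0
        return ad.concat(logits, axis=0), np.array([stop_freq] + bond_freqs)

    def decode(self, z, pool_types, seed=None, rng=None, greedy=False,
               scaffold: Molecule | None = None, name="") -> Molecule:
        """Build one molecule bond-by-bond from a pool of typed atoms.

        The output is connected, valence-valid, uses only pool atoms and is
        deterministic under a fixed seed.  ``scaffold`` optionally seeds the
        partial graph with a starting substructure.
        """
        pool_types = list(pool_types)
        if len(pool_types) > self.max_heavy_atoms:
            raise ValueError(
                f"atom budget {len(pool_types)} exceeds max_heavy_atoms="
                f"{self.max_heavy_atoms}")
        for t in pool_types:
            if t not in self.vocab_:
                raise ValueError(f"atom type {t} not in vocabulary")
        rng = rng if rng is not None else np.random.default_rng(seed)
        params = self.params_
        state = _DecodeState(pool_types, self.vocab_)
        if scaffold is not None:
            kek = kekulized(scaffold)
            _seed_scaffold(state, kek)
        else:
            state.place(int(rng.integers(len(pool_types))))
        while state.queue:
            focus = state.queue[0]
            actions = state.permitted_actions(focus)
            logits, freqs = self._action_scores(state, focus, actions, z,
                                                params)
            probs = ad.softmax(ad.value(logits))
            probs = probs / probs.sum()
            choice = int(np.argmax(probs)) if greedy else \
                int(rng.choice(len(probs), p=probs))
            if choice == 0:
                state.queue.pop(0)
                continue
            u, o = actions[choice - 1]
            newly = not state.placed[u]
            state.add_bond(focus, u, o)
            if newly:
                state.place(u)
        return state.molecule(name)

    # -- training ---------------------------------------------------------

    def _pair_loss(self, pair, params, rng, sample_z=True):
        """Taped loss of translating pair.a into pair.b (teacher forcing)."""
        mu, log_sigma = self.encode(pair.a, params)
        sigma = ad.exp(log_sigma)
        if sample_z:
            eps = rng.standard_normal(self.latent_size)
            z = mu + sigma * eps
        else:
            z = mu
        kl = 0.5 * ((mu * mu + sigma * sigma - 1.0) - 2.0 * log_sigma).sum()

        target = kekulized(pair.b)
        atom_order, steps = construction_trace(target)
        pool_types = [AtomType(a.element, a.charge) for a in target.atoms]
        # atom-type term: predict the pool's type distribution from z
        tidx = np.array([self.vocab_.index(t) for t in pool_types], int)
        q = np.bincount(tidx, minlength=len(self.vocab_)) / len(tidx)
        tlogits = z @ params["type_w"] + params["type_b"]
        type_loss = -((tlogits - ad.logsumexp(tlogits)) * q).sum()

        state = _DecodeState(pool_types, self.vocab_)
        slot_of = {atom_order[0]: atom_order[0]}
        state.place(atom_order[0])
        action_loss = 0.0
        n_steps = 0
        for (focus_t, target_t, order) in steps:
            focus = slot_of[focus_t]
            if state.queue[0] != focus:  # defensive: trace and queue align
                raise RuntimeError("trace/queue desynchronised")
            actions = state.permitted_actions(focus)
            logits, freqs = self._action_scores(state, focus, actions, z,
                                                params)
            if target_t is None:
                chosen = 0
            else:
                if target_t in slot_of:
                    u = slot_of[target_t]
                else:
                    want = pool_types[target_t]
                    u = min(i for i, t in enumerate(state.types)
                            if not state.placed[i] and t == want)
                chosen = 1 + actions.index((u, order))
            s = logits + np.log(freqs)
            fbar = float(freqs.mean())
            action_loss = action_loss + \
                (-fbar) * (s[chosen] - ad.logsumexp(s))
            n_steps += 1
            if target_t is None:
                state.queue.pop(0)
            else:
                newly = not state.placed[u]
                state.add_bond(focus, u, order)
                if newly:
                    slot_of[target_t] = u
                    state.place(u)
        recon = action_loss * (1.0 / max(n_steps, 1)) + type_loss
        return recon, kl

    def fit(self, pairs, validation_pairs=None):
        """Train on molecule pairs; records per-epoch loss history."""
        pairs = list(pairs)
        if not pairs:
            raise ValueError("no training pairs")
        rng = np.random.default_rng(self.random_state)
        self.vocab_ = AtomVocabulary.default()
        valid = [p for p in pairs
                 if check_valence(kekulized(p.a), self.vocab_)[0]
                 and check_valence(kekulized(p.b), self.vocab_)[0]]
        if len(valid) < len(pairs):
            logger.warning("%d pairs dropped (atoms outside vocabulary)",
                           len(pairs) - len(valid))
        pairs = valid
        if not pairs:
            raise ValueError("no vocabulary-valid training pairs")
        kek_targets = [kekulized(p.b) for p in pairs]
        self.freq_table_ = build_frequency_table(
            kek_targets, self.environment_radius)
        self.params_ = _init_params(len(self.vocab_), self.hidden_size,
                                    self.latent_size, self.action_hidden, rng)
        opt = Adam(self.params_, lr=self.learning_rate)
        self.history_ = []
        best = None
        for epoch in range(self.epochs):
            lam = self.lambda_kl
            if self.kl_warmup > 0:
                lam *= min(1.0, (epoch + 1) / self.kl_warmup)
            order = rng.permutation(len(pairs))
            tr_tot = tr_rec = tr_kl = 0.0
            for i in order:
                tparams = {k: Tensor(v) for k, v in self.params_.items()}
                recon, kl = self._pair_loss(pairs[i], tparams, rng)
                total = recon + lam * kl
                if not np.isfinite(ad.value(total)):
                    logger.error("non-finite loss at epoch %d; aborting "
                                 "with last good parameters", epoch)
                    if best is not None:
                        self.params_ = best
                    return self
                total.backward()
                opt.step({k: t.grad for k, t in tparams.items()})
                tr_tot += float(ad.value(total))
                tr_rec += float(ad.value(recon))
                tr_kl += float(ad.value(kl))
            n = len(pairs)
            entry = {"epoch": epoch, "lambda_kl": lam,
                     "train": LossBreakdown(tr_tot / n, tr_rec / n,
                                            tr_kl / n, lam)}
            if validation_pairs:
                va_tot = va_rec = va_kl = 0.0
                vrng = np.random.default_rng(self.random_state + 10_000)
                for p in validation_pairs:
                    recon, kl = self._pair_loss(p, self.params_, vrng,
                                                sample_z=False)
                    va_rec += float(ad.value(recon))
                    va_kl += float(ad.value(kl))
                    va_tot += float(ad.value(recon)) + lam * float(ad.value(kl))
                m = len(validation_pairs)
                entry["validation"] = LossBreakdown(va_tot / m, va_rec / m,
                                                    va_kl / m, lam)
            self.history_.append(entry)
            best = {k: v.copy() for k, v in self.params_.items()}
        return self

    # -- generation -------------------------------------------------------

    def sample(self, active: Molecule, n: int, seed: int = 0,
               max_retries: int = 3):
        """Generate up to ``n`` candidate decoys for one active.

        The atom pool defaults to the active's exact heavy-atom composition,
        so generated candidates match it by construction.  Returns
        ``(molecules, n_failures)``; duplicates are allowed at this stage.
        """
        if n == 0:
            return [], 0
        kek = kekulized(active)
        pool = [AtomType(a.element, a.charge) for a in kek.atoms]
        mu, log_sigma = self.encode(active)
        sigma = np.exp(np.clip(ad.value(log_sigma), -5.0, 2.0))
        mu = ad.value(mu)
        rng = np.random.default_rng(seed)
        out, failures = [], 0
        for k in range(n):
            for attempt in range(max_retries):
                z = mu + sigma * rng.standard_normal(self.latent_size)
                try:
                    mol = self.decode(z, pool, rng=rng)
                    mol.to_rdkit()  # must sanitise
                    ok, _ = check_valence(mol, self.vocab_)
                    if ok:
                        out.append(mol)
                        break
                except Exception:
                    pass
            else:
                failures += 1
        if failures:
            logger.warning("%d/%d generations failed", failures, n)
        return out, failures

    def generate_decoys(self, active, n, seed=0):
        return self.sample(active, n, seed=seed)

    # -- persistence ------------------------------------------------------

    def save(self, path):
        """Single-archive checkpoint: parameters + vocabulary + frequency
        table + config (format version 1)."""
        meta = {"format_version": 1,
                "config": self.get_params(),
                "vocab": [(t.element, t.charge, self.vocab_.valence(t))
                          for t in self.vocab_.types],
                "freq_table": self.freq_table_.to_json()}
        np.savez(path, _meta=np.array(json.dumps(meta)), **self.params_)

    @classmethod
    def load(cls, path) -> "DecoyGenerator":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        model = cls(**meta["config"])
        model.vocab_ = AtomVocabulary(
            [(AtomType(e, c), v) for e, c, v in meta["vocab"]])
        model.freq_table_ = SubgraphFrequencyTable.from_json(
            meta["freq_table"])
        model.params_ = {k: data[k] for k in data.files if k != "_meta"}
        model.history_ = []
        return model


@dataclass(frozen=True)
class LossBreakdown:
    """Total / reconstruction / KL components with the KL weight."""

    total: float
    recon: float
    kl: float
    lambda_kl: float


def _tile(row, n):
    """Stack a (1, d) Tensor/array n times along axis 0."""
    return ad.concat([row] * n, axis=0)


def _seed_scaffold(state: _DecodeState, scaffold: Molecule):
    slots = list(range(len(state.types)))
    assign = {}
    for i, a in enumerate(scaffold.atoms):
        t = AtomType(a.element, a.charge)
        free = [s for s in slots if s not in assign.values()
                and state.types[s] == t]
        if not free:
            raise ValueError(f"scaffold atom {t} not available in pool")
        assign[i] = free[0]
    for i in range(scaffold.n_atoms):
        state.place(assign[i])
    for b in scaffold.bonds:
        state.add_bond(assign[b.i], assign[b.j], b.order)


def train(pairs, validation_pairs=None, **config) -> DecoyGenerator:
    """Functional wrapper: fit a :class:`DecoyGenerator` on pairs."""
    return DecoyGenerator(**config).fit(pairs, validation_pairs)
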