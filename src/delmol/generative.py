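"""Property-regularized variational generative models over fragments.

Two small sequence VAEs share one architecture:

* ``fragvae`` — tokens are directional BRICS fragments of the left-to-right
  scan; the greedy-decoded token sequence is reassembled into a molecule
  (reassembly can fail, so decoded molecules may be flagged invalid).
* ``jtvae`` — tokens are junction-tree cluster labels; the tree decoder
  predicts topology (does another node follow?) and labels, and a
  rule-based graph decoder attaches clusters one at a time, sanitizing the
  intermediate after every attachment, so decoding always yields a
  chemically valid molecule.

The training objective is the beta-weighted evidence lower bound with an
additional property-regression term:

    L = reconstruction + beta * KL(q(z|x) || N(0, I)) + alpha * SE(f(z), y)

with a single-sample Monte-Carlo estimate of the expectations.  The
networks are numpy with hand-written gradients (see :mod:`delmol.nn`).
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem import Molecule, as_molecule
from .fragmentation import (AssemblyError, assemble_tokens, brics_fragment,
                            build_cluster_vocabulary, tree_decompose)
from .nn import Adam, clip_gradients, init_params, softmax, zeros_like_params

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "LossBreakdown",
    "EncoderOutput",
    "OutOfVocabularyError",
    "SequenceVAE",
    "kl_gaussian",
    "elbo_loss",
    "jtvae_reconstruction",
    "pretrain",
    "finetune",
    "assemble_clusters",
]

_CHECKPOINT_VERSION = "delmol-checkpoint-1"


class OutOfVocabularyError(KeyError):
    """A fragment/cluster of the input is absent from the model vocabulary."""


@dataclass
class ModelConfig:
    """Network and training hyperparameters (study defaults)."""

    embedding_size: int = 128
    hidden_size: int = 450
    latent_size: int = 64
    recurrent_layers: int = 1
    learning_rate: float = 1e-4
    batch_size: int = 32
    beta: float = 0.1          # KL weight
    alpha: float = 0.1         # property-regression weight
    property_hidden: int = 32
    fingerprint_bits: int = 128
    max_sequence_length: int = 20

    def __post_init__(self) -> None:
        for name in ("embedding_size", "hidden_size", "latent_size", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beta < 0 or self.alpha < 0:
            raise ValueError("beta and alpha must be non-negative")

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale profile used by the test suite and reduced runs."""
        defaults = dict(embedding_size=32, hidden_size=64, latent_size=16,
                        batch_size=32, learning_rate=3e-3, property_hidden=16,
                        fingerprint_bits=64)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class LossBreakdown:
    reconstruction: float
    kl: float
    property_se: float
    total: float


@dataclass
class EncoderOutput:
    mean: np.ndarray
    log_variance: np.ndarray
    sample: np.ndarray
    epsilon: np.ndarray


def kl_gaussian(mean: np.ndarray, log_variance: np.ndarray) -> float:
    """KL(N(mean, diag exp(log_variance)) || N(0, I)), closed form."""
    mean = np.asarray(mean, dtype=float)
    log_variance = np.asarray(log_variance, dtype=float)
    if mean.shape != log_variance.shape:
        raise ValueError("mean and log-variance differ in length")
    return float(0.5 * np.sum(np.exp(log_variance) + mean ** 2 - 1.0 - log_variance))


def elbo_loss(recon: float, kl: float, prop_se: float,
              beta: float, alpha: float) -> LossBreakdown:
    """Weighted negative ELBO with property regularization."""
    if beta < 0 or alpha < 0:
        raise ValueError("beta and alpha must be non-negative")
    for v in (recon, kl, prop_se):
        if not np.isfinite(v):
            raise ValueError("loss components must be finite")
    return LossBreakdown(reconstruction=recon, kl=kl, property_se=prop_se,
                         total=recon + beta * kl + alpha * prop_se)


def jtvae_reconstruction(topology_loss: float, label_loss: float,
                         subgraph_nll: float, stereo_loss: float = 0.0) -> float:
    """Tree-decoder reconstruction: topology + label (+ graph, + stereo)."""
    parts = (topology_loss, label_loss, subgraph_nll, stereo_loss)
    if any(p < 0 for p in parts):
        raise ValueError("reconstruction components must be non-negative")
    return float(sum(parts))


# ---------------------------------------------------------------------------
# Rule-based graph decoder for the junction-tree model
# ---------------------------------------------------------------------------


def _free_valence_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetImplicitValence() > 0 or a.GetNumExplicitHs() > 0]


def assemble_clusters(cluster_smiles: list[str]) -> Molecule | None:
    """Attach clusters sequentially, sanitizing after every bond formation.

    Each new cluster is bonded to the first chemically acceptable atom pair
    (deterministic atom order); clusters with no acceptable attachment are
    skipped.  Because every accepted intermediate passes sanitization, the
    result is valid by construction.  Returns None only if no cluster
    parses at all.
    """
    current: Chem.Mol | None = None
    for smi in cluster_smiles:
        piece = Chem.MolFromSmiles(smi)
        if piece is None:
            continue
        if current is None:
            current = piece
            continue
        attached = None
        for u in _free_valence_atoms(current):
            for v in _free_valence_atoms(piece):
                combo = Chem.RWMol(Chem.CombineMols(current, piece))
                combo.AddBond(u, current.GetNumAtoms() + v, Chem.BondType.SINGLE)
                candidate = combo.GetMol()
                try:
                    Chem.SanitizeMol(candidate)
                except Exception:
                    continue
                attached = candidate
                break
            if attached is not None:
                break
        if attached is not None:
            current = attached
    if current is None:
        return None
    return Molecule.from_smiles(Chem.MolToSmiles(current))


# ---------------------------------------------------------------------------
# The sequence VAE
# ---------------------------------------------------------------------------


class SequenceVAE:
    """Shared VAE over fragment or junction-tree token sequences.

    ``kind='fragvae'`` uses one encoder over fragment counts and a decoder
    with an end-of-sequence class.  ``kind='jtvae'`` uses a two-part latent
    z = [z_T, z_G] (tree encoder over cluster counts, graph encoder over a
    folded circular fingerprint); the decoder consumes z_T and carries a
    separate topology head, and label prediction has no EOS class.
    """

    def __init__(self, vocab: list[str], config: ModelConfig,
                 kind: str = "jtvae", seed: int = 0) -> None:
        if kind not in ("fragvae", "jtvae"):
            raise ValueError("kind must be 'fragvae' or 'jtvae'")
        if not vocab:
            raise ValueError("empty vocabulary")
        self.kind = kind
        self.config = config
        self.vocab = list(vocab)
        self.token_to_id = {t: i for i, t in enumerate(self.vocab)}
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self._fpgen = rdFingerprintGenerator.GetMorganGenerator(
            radius=2, fpSize=config.fingerprint_bits)
        self.prop_mean = np.zeros(3)
        self.prop_std = np.ones(3)

        V = len(self.vocab)
        L = config.latent_size
        H = config.hidden_size
        D = config.embedding_size
        Hp = config.property_hidden
        if kind == "jtvae":
            self.lt = L // 2
            self.lg = L - self.lt
            enc_shapes = {
                "encT_W1": (H, V), "encT_b1": (H,),
                "encT_Wm": (self.lt, H), "encT_bm": (self.lt,),
                "encT_Wv": (self.lt, H), "encT_bv": (self.lt,),
                "encG_W1": (H, config.fingerprint_bits), "encG_b1": (H,),
                "encG_Wm": (self.lg, H), "encG_bm": (self.lg,),
                "encG_Wv": (self.lg, H), "encG_bv": (self.lg,),
            }
            dec_in = self.lt
            n_out = V          # labels only; topology head handles stopping
        else:
            self.lt = L
            self.lg = 0
            enc_shapes = {
                "encT_W1": (H, V), "encT_b1": (H,),
                "encT_Wm": (L, H), "encT_bm": (L,),
                "encT_Wv": (L, H), "encT_bv": (L,),
            }
            dec_in = L
            n_out = V + 1      # + end-of-sequence class
        self.eos_id = V if kind == "fragvae" else None
        self.sos_row = V       # embedding row used as start-of-sequence input

        shapes = dict(enc_shapes)
        shapes.update({
            "dec_emb": (V + 1, D),
            "dec_Wz": (H, dec_in), "dec_bz": (H,),
            "dec_Whh": (H, H), "dec_Wxh": (H, D), "dec_bh": (H,),
            "dec_Wo": (n_out, H), "dec_bo": (n_out,),
            "prop_W1": (Hp, L), "prop_b1": (Hp,),
            "prop_W2": (3, Hp), "prop_b2": (3,),
        })
        if kind == "jtvae":
            shapes.update({"dec_topo_w": (H,), "dec_topo_b": (1,)})
        self.params = init_params(np.random.default_rng(seed), shapes)
        self.opt = Adam(self.params)

    # -- tokenization -------------------------------------------------------

    @classmethod
    def from_dataset(cls, mols, config: ModelConfig, kind: str = "jtvae",
                     seed: int = 0) -> "SequenceVAE":
        mols = [as_molecule(m) for m in mols]
        if kind == "jtvae":
            vocab_obj = build_cluster_vocabulary(mols)
            vocab = sorted(vocab_obj.entries, key=vocab_obj.entries.get)
        else:
            counts: dict[str, int] = {}
            for m in mols:
                for t in brics_fragment(m).tokens:
                    counts[t] = counts.get(t, 0) + 1
            vocab = sorted(counts, key=lambda t: (-counts[t], t))
        return cls(vocab=vocab, config=config, kind=kind, seed=seed)

    def tokenize(self, mol: Molecule | str) -> list[int]:
        """Token-id sequence of a molecule; raises on out-of-vocabulary."""
        mol = as_molecule(mol)
        if self.kind == "fragvae":
            tokens = brics_fragment(mol).tokens
        else:
            jt = tree_decompose(mol)
            labels = jt.cluster_smiles(mol.require_valid())
            tokens = _dfs_order(labels, jt.edges)
        ids = []
        for t in tokens:
            if t not in self.token_to_id:
                raise OutOfVocabularyError(t)
            ids.append(self.token_to_id[t])
        return ids[: self.config.max_sequence_length]

    def _features(self, mol: Molecule, ids: list[int]) -> dict[str, np.ndarray]:
        xT = np.zeros(len(self.vocab))
        for i in ids:
            xT[i] += 1.0
        feats = {"xT": xT}
        if self.kind == "jtvae":
            fp = self._fpgen.GetFingerprint(mol.require_valid())
            xG = np.zeros(self.config.fingerprint_bits)
            for bit in fp.GetOnBits():
                xG[bit] = 1.0
            feats["xG"] = xG
        return feats

    # -- encoder ------------------------------------------------------------

    def _encode_part(self, prefix: str, x: np.ndarray):
        p = self.params
        pre = p[f"{prefix}_W1"] @ x + p[f"{prefix}_b1"]
        h = np.tanh(pre)
        mu = p[f"{prefix}_Wm"] @ h + p[f"{prefix}_bm"]
        lv = np.clip(p[f"{prefix}_Wv"] @ h + p[f"{prefix}_bv"], -10.0, 10.0)
        return mu, lv, h

    def encode(self, mol: Molecule | str) -> EncoderOutput:
        mol = as_molecule(mol)
        ids = self.tokenize(mol)
        feats = self._features(mol, ids)
        mu_t, lv_t, _ = self._encode_part("encT", feats["xT"])
        if self.kind == "jtvae":
            mu_g, lv_g, _ = self._encode_part("encG", feats["xG"])
            mu = np.concatenate([mu_t, mu_g])
            lv = np.concatenate([lv_t, lv_g])
        else:
            mu, lv = mu_t, lv_t
        eps = self._rng.standard_normal(mu.shape)
        return EncoderOutput(mean=mu, log_variance=lv,
                             sample=mu + np.exp(lv / 2.0) * eps, epsilon=eps)

    # -- decoder (greedy generation) ---------------------------------------

    def _decode_ids(self, z: np.ndarray) -> list[int]:
        p = self.params
        z = np.asarray(z, dtype=float)
        if z.shape[0] != self.config.latent_size:
            raise ValueError("latent vector has the wrong length")
        z_dec = z[: self.lt] if self.kind == "jtvae" else z
        s = np.tanh(p["dec_Wz"] @ z_dec + p["dec_bz"])
        ids: list[int] = []
        prev_row = self.sos_row
        for _ in range(self.config.max_sequence_length):
            x = p["dec_emb"][prev_row]
            s = np.tanh(p["dec_Whh"] @ s + p["dec_Wxh"] @ x + p["dec_bh"])
            if self.kind == "jtvae":
                topo = float(p["dec_topo_w"] @ s + p["dec_topo_b"][0])
                if topo < 0.0:  # sigmoid(topo) < 0.5 -> stop
                    break
                tok = int(np.argmax(p["dec_Wo"] @ s + p["dec_bo"]))
            else:
                tok = int(np.argmax(p["dec_Wo"] @ s + p["dec_bo"]))
                if tok == self.eos_id:
                    break
            ids.append(tok)
            prev_row = tok
        return ids

    def decode(self, z: np.ndarray) -> Molecule | None:
        """Greedy decode; junction-tree assembly is valid by construction."""
        ids = self._decode_ids(z)
        if self.kind == "jtvae":
            if not ids:
                ids = [0]  # degenerate latent: fall back to the top cluster
            return assemble_clusters([self.vocab[i] for i in ids])
        if not ids:
            return None
        try:
            return assemble_tokens([self.vocab[i] for i in ids])
        except AssemblyError:
            return Molecule(smiles=".".join(self.vocab[i] for i in ids),
                            graph=None, valid=False)

    def sample_prior(self, n: int, seed: int = 0) -> list[Molecule]:
        """Decode n latent vectors drawn from the standard-normal prior."""
        if n < 0:
            raise ValueError("n must be non-negative")
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            z = rng.standard_normal(self.config.latent_size)
            mol = self.decode(z)
            out.append(mol if mol is not None
                       else Molecule(smiles="", graph=None, valid=False))
        return out

    # -- training -----------------------------------------------------------

    def _example_grads(self, mol: Molecule, ids: list[int],
                       y: np.ndarray | None, grads: dict[str, np.ndarray],
                       w_recon: float, w_kl: float, w_se: float,
                       rng: np.random.Generator):
        """Forward + backward for one molecule; returns loss components."""
        p = self.params
        feats = self._features(mol, ids)

        # ---- encoder forward
        parts = [("encT", feats["xT"])]
        if self.kind == "jtvae":
            parts.append(("encG", feats["xG"]))
        mus, lvs, hs = [], [], []
        for prefix, x in parts:
            mu, lv, h = self._encode_part(prefix, x)
            mus.append(mu)
            lvs.append(lv)
            hs.append(h)
        mu = np.concatenate(mus)
        lv = np.concatenate(lvs)
        eps = rng.standard_normal(mu.shape)
        std = np.exp(lv / 2.0)
        z = mu + std * eps
        kl = kl_gaussian(mu, lv)

        # ---- decoder forward (teacher forcing)
        z_dec = z[: self.lt] if self.kind == "jtvae" else z
        pre0 = p["dec_Wz"] @ z_dec + p["dec_bz"]
        s = np.tanh(pre0)
        states = [s]
        inputs = [self.sos_row] + list(ids)
        probs_seq, topo_seq = [], []
        n_steps = len(ids) + 1
        recon = 0.0
        topo_loss = 0.0
        for t in range(n_steps):
            x = p["dec_emb"][inputs[t]]
            s = np.tanh(p["dec_Whh"] @ states[-1] + p["dec_Wxh"] @ x + p["dec_bh"])
            states.append(s)
            if self.kind == "jtvae":
                a = float(p["dec_topo_w"] @ s + p["dec_topo_b"][0])
                target = 1.0 if t < len(ids) else 0.0
                # stable BCE with logits
                topo_loss += max(a, 0.0) - a * target + np.log1p(np.exp(-abs(a)))
                topo_seq.append((a, target))
                if t < len(ids):
                    pr = softmax(p["dec_Wo"] @ s + p["dec_bo"])
                    recon += -np.log(max(pr[ids[t]], 1e-12))
                    probs_seq.append(pr)
                else:
                    probs_seq.append(None)
            else:
                pr = softmax(p["dec_Wo"] @ s + p["dec_bo"])
                target = ids[t] if t < len(ids) else self.eos_id
                recon += -np.log(max(pr[target], 1e-12))
                probs_seq.append(pr)
        recon += topo_loss

        # ---- property head forward
        se = 0.0
        if y is not None:
            hp_pre = p["prop_W1"] @ z + p["prop_b1"]
            hp = np.tanh(hp_pre)
            yhat = p["prop_W2"] @ hp + p["prop_b2"]
            diff = yhat - y
            se = float(diff @ diff)

        # ---- backward
        dz = np.zeros_like(z)
        if y is not None and w_se:
            dyhat = 2.0 * diff * w_se
            grads["prop_W2"] += np.outer(dyhat, hp)
            grads["prop_b2"] += dyhat
            dhp = (p["prop_W2"].T @ dyhat) * (1 - hp ** 2)
            grads["prop_W1"] += np.outer(dhp, z)
            grads["prop_b1"] += dhp
            dz += p["prop_W1"].T @ dhp

        ds_next = np.zeros(self.config.hidden_size)
        for t in range(n_steps, 0, -1):
            s_t = states[t]
            ds = ds_next
            if self.kind == "jtvae":
                a, target = topo_seq[t - 1]
                dtopo = (1.0 / (1.0 + np.exp(-a)) - target) * w_recon
                grads["dec_topo_w"] += dtopo * s_t
                grads["dec_topo_b"][0] += dtopo
                ds = ds + dtopo * p["dec_topo_w"]
                pr = probs_seq[t - 1]
                if pr is not None:
                    dlog = pr * w_recon
                    dlog[ids[t - 1]] -= w_recon
                    grads["dec_Wo"] += np.outer(dlog, s_t)
                    grads["dec_bo"] += dlog
                    ds = ds + p["dec_Wo"].T @ dlog
            else:
                pr = probs_seq[t - 1]
                target = ids[t - 1] if t - 1 < len(ids) else self.eos_id
                dlog = pr * w_recon
                dlog[target] -= w_recon
                grads["dec_Wo"] += np.outer(dlog, s_t)
                grads["dec_bo"] += dlog
                ds = ds + p["dec_Wo"].T @ dlog
            dpre = ds * (1 - s_t ** 2)
            grads["dec_Whh"] += np.outer(dpre, states[t - 1])
            x_row = inputs[t - 1]
            grads["dec_Wxh"] += np.outer(dpre, p["dec_emb"][x_row])
            grads["dec_emb"][x_row] += p["dec_Wxh"].T @ dpre
            grads["dec_bh"] += dpre
            ds_next = p["dec_Whh"].T @ dpre
        dpre0 = ds_next * (1 - states[0] ** 2)
        grads["dec_Wz"] += np.outer(dpre0, z_dec)
        grads["dec_bz"] += dpre0
        dz_dec = p["dec_Wz"].T @ dpre0
        if self.kind == "jtvae":
            dz[: self.lt] += dz_dec
        else:
            dz += dz_dec

        # reparameterization + KL into encoder parts
        dmu_total = dz + w_kl * mu
        dlv_total = dz * 0.5 * std * eps + w_kl * 0.5 * (np.exp(lv) - 1.0)
        offset = 0
        for (prefix, x), h in zip(parts, hs):
            size = mus[0].shape[0] if prefix == "encT" else self.lg
            dmu = dmu_total[offset: offset + size]
            dlv = dlv_total[offset: offset + size]
            grads[f"{prefix}_Wm"] += np.outer(dmu, h)
            grads[f"{prefix}_bm"] += dmu
            grads[f"{prefix}_Wv"] += np.outer(dlv, h)
            grads[f"{prefix}_bv"] += dlv
            dh = p[f"{prefix}_Wm"].T @ dmu + p[f"{prefix}_Wv"].T @ dlv
            dpre = dh * (1 - h ** 2)
            grads[f"{prefix}_W1"] += np.outer(dpre, x)
            grads[f"{prefix}_b1"] += dpre
            offset += size
        return float(recon), float(kl), float(se)

    def fit(self, mols, epochs: int, lr: float | None = None,
            targets: dict | None = None) -> list[dict]:
        """Train for ``epochs`` epochs; returns the per-epoch loss log.

        ``targets`` maps canonical SMILES to ObjectiveVector-like objects;
        property targets are standardized over the supplied fit set.
        Molecules whose tokens fall outside the vocabulary are skipped.
        """
        mols = [as_molecule(m) for m in mols]
        if not mols:
            raise ValueError("empty training set")
        lr = self.config.learning_rate if lr is None else lr
        examples = []
        for m in mols:
            if not m.valid:
                continue
            try:
                ids = self.tokenize(m)
            except OutOfVocabularyError as exc:
                logger.debug("skipping %s: OOV token %s", m.smiles, exc)
                continue
            if ids:
                examples.append((m, ids))
        if not examples:
            raise ValueError("no trainable molecules (all empty or out of vocabulary)")

        y_map = {}
        if targets:
            raw = []
            for m, _ in examples:
                t = targets.get(m.smiles)
                if t is not None:
                    vec = t.as_tuple() if hasattr(t, "as_tuple") else tuple(t)
                    raw.append((m.smiles, np.asarray(vec, dtype=float)))
            if raw:
                arr = np.stack([v for _, v in raw])
                self.prop_mean = arr.mean(axis=0)
                self.prop_std = np.where(arr.std(axis=0) > 1e-9,
                                         arr.std(axis=0), 1.0)
                y_map = {s: (v - self.prop_mean) / self.prop_std for s, v in raw}

        cfg = self.config
        log: list[dict] = []
        order = np.arange(len(examples))
        for epoch in range(epochs):
            self._rng.shuffle(order)
            sums = np.zeros(3)
            for start in range(0, len(order), cfg.batch_size):
                batch = [examples[i] for i in order[start: start + cfg.batch_size]]
                grads = zeros_like_params(self.params)
                w = 1.0 / len(batch)
                br = bk = bs = 0.0
                for m, ids in batch:
                    y = y_map.get(m.smiles)
                    r, k, s = self._example_grads(
                        m, ids, y, grads, w_recon=w, w_kl=cfg.beta * w,
                        w_se=cfg.alpha * w, rng=self._rng)
                    br += r / len(batch)
                    bk += k / len(batch)
                    bs += s / len(batch)
                clip_gradients(grads)
                self.opt.step(self.params, grads, lr)
                sums += np.array([br, bk, bs]) * len(batch)
            means = sums / len(examples)
            breakdown = elbo_loss(means[0], means[1], means[2],
                                  cfg.beta, cfg.alpha)
            if not np.isfinite(breakdown.total):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: {breakdown}")
            log.append({"epoch": epoch, "reconstruction": breakdown.reconstruction,
                        "kl": breakdown.kl, "property_se": breakdown.property_se,
                        "total": breakdown.total, "lr": lr})
        return log

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        header = {"version": _CHECKPOINT_VERSION, "kind": self.kind,
                  "seed": self.seed, "vocab": self.vocab,
                  "config": asdict(self.config),
                  "prop_mean": self.prop_mean.tolist(),
                  "prop_std": self.prop_std.tolist()}
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        np.savez(path, header=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path) -> "SequenceVAE":
        data = np.load(path, allow_pickle=False)
        header = json.loads(str(data["header"]))
        if header.get("version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {header.get('version')}")
        model = cls(vocab=header["vocab"], config=ModelConfig(**header["config"]),
                    kind=header["kind"], seed=header["seed"])
        for k in model.params:
            model.params[k] = data[f"param_{k}"]
        model.prop_mean = np.asarray(header["prop_mean"])
        model.prop_std = np.asarray(header["prop_std"])
        return model


def _dfs_order(labels: list[str], edges: list[tuple[int, int]]) -> list[str]:
    """Depth-first preorder of junction-tree labels from node 0."""
    adj: dict[int, list[int]] = {i: [] for i in range(len(labels))}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen: set[int] = set()
    order: list[str] = []
    for root in range(len(labels)):
        if root in seen:
            continue
        stack = [root]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            order.append(labels[node])
            stack.extend(sorted(adj[node], reverse=True))
    return order


def pretrain(mols, config: ModelConfig, epochs: int, kind: str = "jtvae",
             seed: int = 0, targets: dict | None = None) -> tuple[SequenceVAE, list[dict]]:
    """Build a model from a dataset and train it from scratch."""
    model = SequenceVAE.from_dataset(mols, config, kind=kind, seed=seed)
    log = model.fit(mols, epochs=epochs, targets=targets)
    return model, log


def finetune(model: SequenceVAE, mols, epochs: int, generation: int,
             annealing_rate: float = 0.8, targets: dict | None = None) -> list[dict]:
    """Continue training with the generation-annealed learning rate."""
    lr = model.config.learning_rate * annealing_rate ** generation
    return model.fit(mols, epochs=epochs, lr=lr, targets=targets)
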