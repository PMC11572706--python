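"""Keyword-block configuration dialect.

Configurations are brace-delimited keyword blocks, mirroring the keyword
vocabulary of collective-variable modules in biomolecular MD codes::

    engine {
        potential double_well_1d
        parameter h 2.0
        temperature 300.0
        timestep 1.0
        friction 20.0
        seed 7
        masses 1.0
        initialPositions -1.0 0.0 0.0
    }
    colvar {
        name x
        distanceZ { atomNumbers 1  axis 1 0 0 }
    }
    metadynamics {
        colvars x
        lowerBoundary -1.7
        upperBoundary 1.7
        bins 68
        gaussianSigmas 0.1
        hillWeight 0.08
        newHillFrequency 500
    }

Atom numbers are 1-based in files (0-based internally).  Unknown keywords
are rejected with their line number; ``hillWidth`` and ``gaussianSigmas``
are mutually exclusive; biases referencing undeclared colvars are errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import restraints
from .abf import AbfBias, EabfBias
from .engine import EngineParams, Simulation, SystemState
from .expressions import CustomExpressionComponent, ExpressionSpec
from .geometry import (Angle, AtomGroup, Distance, DistanceXY, DistanceZ,
                       PolarPhi, PolarTheta)
from .grids import Grid
from .metad import EbmetadSpec, MetadBias, MetadState
from .neural import NeuralNetworkCV, load_network
from .potentials import PotentialSpec

__all__ = ["ConfigError", "Block", "parse_config", "build_simulation"]


class ConfigError(ValueError):
    pass


@dataclass
class Block:
    name: str
    line: int
    keywords: list = field(default_factory=list)  # (key, value string, line)
    blocks: list = field(default_factory=list)

    def get(self, key, default=None):
        for k, v, _ in self.keywords:
            if k == key:
                return v
        return default

    def require(self, key):
        v = self.get(key)
        if v is None:
            raise ConfigError(f"block '{self.name}' (line {self.line}) "
                              f"is missing required keyword '{key}'")
        return v

    def floats(self, key, default=None):
        v = self.get(key)
        if v is None:
            return default
        return [float(t) for t in v.split()]

    def child(self, name):
        for b in self.blocks:
            if b.name == name:
                return b
        return None


def _tokenize_blocks(text: str) -> list:
    """Parse brace-delimited blocks; keeps line numbers for errors."""
    root = Block("(root)", 0)
    stack = [root]
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        while line:
            if line == "}":
                if len(stack) == 1:
                    raise ConfigError(f"unbalanced '}}' at line {lineno}")
                stack.pop()
                line = ""
            elif line.endswith("{"):
                name = line[:-1].strip()
                if not name:
                    raise ConfigError(f"anonymous block at line {lineno}")
                blk = Block(name, lineno)
                stack[-1].blocks.append(blk)
                stack.append(blk)
                line = ""
            elif "{" in line:
                # inline block:  name { key val ... }
                name, rest = line.split("{", 1)
                blk = Block(name.strip(), lineno)
                stack[-1].blocks.append(blk)
                stack.append(blk)
                if not rest.strip().endswith("}"):
                    raise ConfigError(f"inline block not closed at line {lineno}")
                inner = rest.strip()[:-1].strip()
                # inline contents: alternating key/value pairs per keyword
                if inner:
                    toks = inner.split()
                    i = 0
                    while i < len(toks):
                        key = toks[i]
                        vals = []
                        i += 1
                        while i < len(toks) and _is_number(toks[i]):
                            vals.append(toks[i])
                            i += 1
                        blk.keywords.append((key, " ".join(vals), lineno))
                stack.pop()
                line = ""
            else:
                parts = line.split(None, 1)
                key = parts[0]
                val = parts[1] if len(parts) > 1 else ""
                stack[-1].keywords.append((key, val, lineno))
                line = ""
    if len(stack) != 1:
        raise ConfigError(f"unclosed block '{stack[-1].name}' "
                          f"(opened at line {stack[-1].line})")
    return root.blocks


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


_TOP_BLOCKS = {"engine", "colvar", "harmonic", "abf", "metadynamics",
               "ebmeta", "alb", "rad", "histogramRestraint", "abmd"}

_KNOWN_KEYWORDS = {
    "engine": {"potential", "parameter", "temperature", "friction",
               "timestep", "seed", "masses", "initialPositions",
               "boltzmannConstant"},
    "colvar": {"name", "customFunction", "inputs", "neuralNetwork",
               "weightsFile", "outputIndex"},
    "component": {"atomNumbers", "axis", "weights", "group1", "group2",
                  "group3", "refGroup"},
    "harmonic": {"colvars", "centers", "forceConstant"},
    "abf": {"colvars", "lowerBoundary", "upperBoundary", "bins",
            "fullSamples", "extendedLagrangian", "extendedFluctuation",
            "extendedTimeConstant"},
    "metadynamics": {"colvars", "lowerBoundary", "upperBoundary", "bins",
                     "hillWeight", "newHillFrequency", "gaussianSigmas",
                     "hillWidth", "wellTemperedDeltaT", "useHillsReflection",
                     "reflectionRange", "targetDistributionFile",
                     "replicaID"},
    # ebmeta: metadynamics with a mandatory target distribution
    "ebmeta": {"colvars", "lowerBoundary", "upperBoundary", "bins",
               "hillWeight", "newHillFrequency", "gaussianSigmas",
               "hillWidth", "useHillsReflection", "reflectionRange",
               "targetDistributionFile", "replicaID"},
    "alb": {"colvars", "centers", "learningRate", "updatePeriod", "ewmaTau"},
    "rad": {"colvars", "centers", "errors", "learningRate", "updatePeriod",
            "ewmaTau", "agreement"},
    "histogramRestraint": {"colvars", "lowerBoundary", "upperBoundary",
                           "kernels", "kernelWidth", "forceConstant",
                           "targets", "kernelType"},
    "abmd": {"colvars", "forceConstant", "stopValue", "decrease"},
}

_COMPONENT_KINDS = {"distance", "distanceZ", "distanceXY", "angle",
                    "polarTheta", "polarPhi"}


def parse_config(text: str) -> list:
    """Parse and validate a configuration into top-level blocks."""
    if not text.strip():
        raise ConfigError("empty configuration")
    blocks = _tokenize_blocks(text)
    for blk in blocks:
        if blk.name not in _TOP_BLOCKS:
            raise ConfigError(f"unknown block '{blk.name}' at line {blk.line}")
        known = _KNOWN_KEYWORDS[blk.name]
        for key, _, line in blk.keywords:
            if key not in known:
                raise ConfigError(
                    f"unknown keyword '{key}' in block '{blk.name}' "
                    f"at line {line}")
        if blk.name in ("metadynamics", "ebmeta"):
            if blk.get("gaussianSigmas") is not None \
                    and blk.get("hillWidth") is not None:
                raise ConfigError(
                    f"block '{blk.name}' at line {blk.line}: gaussianSigmas "
                    f"is mutually exclusive with the hillWidth option")
            if blk.name == "ebmeta" and blk.get("targetDistributionFile") is None:
                raise ConfigError(
                    f"block 'ebmeta' at line {blk.line} requires "
                    f"targetDistributionFile")
        if blk.name == "colvar":
            for sub in blk.blocks:
                if sub.name not in _COMPONENT_KINDS:
                    raise ConfigError(f"unknown colvar component '{sub.name}' "
                                      f"at line {sub.line}")
                for key, _, line in sub.keywords:
                    if key not in _KNOWN_KEYWORDS["component"]:
                        raise ConfigError(
                            f"unknown keyword '{key}' in component "
                            f"'{sub.name}' at line {line}")
    return blocks


def _atom_group(block: Block) -> AtomGroup:
    nums = block.get("atomNumbers")
    if nums is None:
        raise ConfigError(f"component at line {block.line} needs atomNumbers")
    indices = [int(t) - 1 for t in nums.split()]  # 1-based in files
    weights = block.floats("weights")
    return AtomGroup(indices, weights)


def _build_component(block: Block):
    kind = block.name
    if kind in ("distance", "distanceXY", "angle"):
        groups = []
        for gname in ("group1", "group2", "group3"):
            sub = block.child(gname)
            if sub is not None:
                groups.append(_atom_group(sub))
        if not groups:  # single flat atomNumbers list = two 1-atom groups
            raise ConfigError(f"'{kind}' at line {block.line} needs "
                              f"group1/group2 sub-blocks")
        if kind == "distance":
            return Distance(*groups[:2])
        if kind == "distanceXY":
            axis = block.floats("axis", [0.0, 0.0, 1.0])
            return DistanceXY(groups[0], groups[1], axis=axis)
        return Angle(*groups[:3])
    if kind == "distanceZ":
        g1 = block.child("group1")
        ref = block.child("refGroup")
        main = _atom_group(g1) if g1 is not None else _atom_group(block)
        axis = block.floats("axis", [0.0, 0.0, 1.0])
        return DistanceZ(main, _atom_group(ref) if ref else None, axis=axis)
    if kind in ("polarTheta", "polarPhi"):
        g1 = block.child("group1")
        ref = block.child("refGroup")
        main = _atom_group(g1) if g1 is not None else _atom_group(block)
        cls = PolarTheta if kind == "polarTheta" else PolarPhi
        return cls(main, _atom_group(ref) if ref else None)
    raise ConfigError(f"unsupported component '{kind}' at line {block.line}")


@dataclass
class BuiltConfig:
    simulation: Simulation
    cv_names: list


def build_simulation(blocks: list) -> BuiltConfig:
    """Construct a runnable Simulation from parsed blocks."""
    eng = next((b for b in blocks if b.name == "engine"), None)
    if eng is None:
        raise ConfigError("configuration needs an engine block")
    pot_kind = eng.require("potential")
    pot_params = {}
    for key, val, _ in eng.keywords:
        if key == "parameter":
            toks = val.split()
            pot_params[toks[0]] = float(toks[1])
    potential = PotentialSpec(pot_kind, pot_params)
    params = EngineParams(
        temperature=float(eng.get("temperature", 300.0)),
        friction=float(eng.get("friction", 10.0)),
        timestep=float(eng.get("timestep", 1.0)),
        seed=int(eng.get("seed", 1)))
    kb = eng.get("boltzmannConstant")
    if kb is not None:
        params.boltzmann_constant = float(kb)
    masses = np.array(eng.floats("masses", [1.0]))
    pos0 = np.array(eng.floats("initialPositions",
                               [0.0] * (3 * len(masses)))).reshape(-1, 3)
    if len(pos0) != len(masses):
        raise ConfigError("initialPositions count does not match masses")
    state = SystemState(pos0, np.zeros_like(pos0), masses)

    colvars, cv_names = [], []
    for blk in (b for b in blocks if b.name == "colvar"):
        name = blk.require("name")
        if name in cv_names:
            raise ConfigError(f"duplicate colvar name '{name}' at line {blk.line}")
        expr = blk.get("customFunction")
        nn = blk.get("weightsFile")
        if expr is not None:
            labels = blk.require("inputs").split()
            children = []
            for lab in labels:
                if lab not in cv_names:
                    raise ConfigError(
                        f"colvar '{name}' (line {blk.line}) references "
                        f"undefined colvar '{lab}'")
                children.append(colvars[cv_names.index(lab)])
            comp = CustomExpressionComponent(ExpressionSpec(expr, labels),
                                             children)
        elif nn is not None:
            labels = blk.require("inputs").split()
            children = []
            for lab in labels:
                if lab not in cv_names:
                    raise ConfigError(
                        f"colvar '{name}' (line {blk.line}) references "
                        f"undefined colvar '{lab}'")
                children.append(colvars[cv_names.index(lab)])
            spec = load_network(nn)
            comp = NeuralNetworkCV(spec, children,
                                   int(blk.get("outputIndex", 0)))
        else:
            if not blk.blocks:
                raise ConfigError(f"colvar '{name}' (line {blk.line}) "
                                  f"declares no component")
            comp = _build_component(blk.blocks[0])
        colvars.append(comp)
        cv_names.append(name)

    def cv_index(blk: Block) -> int:
        ref = blk.require("colvars").split()[0]
        if ref not in cv_names:
            raise ConfigError(f"bias '{blk.name}' (line {blk.line}) references "
                              f"undefined colvar '{ref}'")
        return cv_names.index(ref)

    biases = []
    kT = params.boltzmann_constant * params.temperature
    for blk in blocks:
        if blk.name == "harmonic":
            i = cv_index(blk)
            biases.append(restraints.HarmonicRestraint(
                i, float(blk.require("centers")),
                float(blk.require("forceConstant")),
                periodic=colvars[i].periodic, period=colvars[i].period))
        elif blk.name == "abf":
            i = cv_index(blk)
            grid = Grid.make([float(blk.require("lowerBoundary"))],
                             [float(blk.require("upperBoundary"))],
                             [int(blk.get("bins", 40))])
            full = int(blk.get("fullSamples", 200))
            if blk.get("extendedLagrangian", "off") == "on":
                sigma = float(blk.get("extendedFluctuation", 0.1))
                tau = float(blk.get("extendedTimeConstant", 40.0))
                coupling = kT / sigma ** 2
                mass = coupling * (tau / (2.0 * math.pi)) ** 2
                biases.append(EabfBias(i, grid, coupling, ext_mass=mass,
                                       full_samples=full))
            else:
                biases.append(AbfBias(i, grid, full_samples=full))
        elif blk.name in ("metadynamics", "ebmeta"):
            idx = [cv_names.index(n) if n in cv_names else
                   _raise_cv(blk, n) for n in blk.require("colvars").split()]
            los = blk.floats("lowerBoundary")
            his = blk.floats("upperBoundary")
            bins = [int(t) for t in blk.require("bins").split()]
            grid = Grid.make(los, his, bins)
            w0 = float(blk.get("hillWeight", 0.01))
            dT = blk.get("wellTemperedDeltaT") if blk.name == "metadynamics" else None
            sig = blk.floats("gaussianSigmas")
            if sig is None:
                hw = float(blk.get("hillWidth", 2.0))
                ms = MetadState.from_hill_width(
                    grid, hw, w0,
                    reflecting=blk.get("useHillsReflection", "off") == "on",
                    reflection_range=float(blk.get("reflectionRange", 6.0)),
                    well_tempered_delta_t=None if dT is None else float(dT))
            else:
                ms = MetadState(
                    grid, np.array(sig), w0,
                    reflecting=blk.get("useHillsReflection", "off") == "on",
                    reflection_range=float(blk.get("reflectionRange", 6.0)),
                    well_tempered_delta_t=None if dT is None else float(dT))
            target = None
            tfile = blk.get("targetDistributionFile")
            if tfile is not None:
                from .grids import read_grid
                tgrid, arrays = read_grid(tfile)
                target = EbmetadSpec(tgrid, arrays["density"])
            biases.append(MetadBias(idx, ms,
                                    period=int(blk.get("newHillFrequency", 500)),
                                    target=target,
                                    replica_id=int(blk.get("replicaID", 0))))
        elif blk.name == "alb":
            biases.append(restraints.AlbBias(
                cv_index(blk), float(blk.require("centers")),
                float(blk.require("learningRate")),
                update_period=int(blk.get("updatePeriod", 100)),
                ewma_tau=float(blk.get("ewmaTau", 500.0))))
        elif blk.name == "rad":
            biases.append(restraints.RadBias(
                cv_index(blk), float(blk.require("centers")),
                float(blk.require("errors")),
                float(blk.require("learningRate")),
                update_period=int(blk.get("updatePeriod", 100)),
                ewma_tau=float(blk.get("ewmaTau", 500.0)),
                agreement=float(blk.get("agreement", 1.0))))
        elif blk.name == "abmd":
            biases.append(restraints.AbmdBias(
                cv_index(blk), float(blk.require("forceConstant")),
                float(blk.require("stopValue")),
                decrease=blk.get("decrease", "off") == "on"))
        elif blk.name == "histogramRestraint":
            i = cv_index(blk)
            lo = float(blk.require("lowerBoundary"))
            hi = float(blk.require("upperBoundary"))
            n = int(blk.require("kernels"))
            centers = np.linspace(lo, hi, n)
            spec = restraints.HistRestraintSpec(
                centers, float(blk.require("kernelWidth")),
                float(blk.require("forceConstant")),
                np.array(blk.floats("targets", [0.0] * n)),
                kernel=blk.get("kernelType", "gaussian"), n_replicas=1)
            biases.append(_HistBias(i, spec))
    sim = Simulation(potential, params, state, colvars=colvars, biases=biases)
    return BuiltConfig(sim, cv_names)


def _raise_cv(blk, name):
    raise ConfigError(f"bias '{blk.name}' (line {blk.line}) references "
                      f"undefined colvar '{name}'")


class _HistBias:
    """Single-replica histogram restraint adapter for the Simulation loop."""

    def __init__(self, cv_index: int, spec):
        self.cv_index = cv_index
        self.spec = spec

    def update_and_force(self, cv_values, sim):
        from .restraints import histogram_restraint_force
        out = [0.0] * len(cv_values)
        _, forces = histogram_restraint_force(self.spec,
                                              [cv_values[self.cv_index]])
        out[self.cv_index] = float(forces[0])
        return out

    def state_dict(self):
        return {}

    def load_state_dict(self, doc):
        pass
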