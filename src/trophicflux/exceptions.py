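"""Exception hierarchy for trophicflux.

Every error raised on purpose by the library derives from
:class:`TrophicfluxError`, so callers (and the CLI) can map error classes
to exit codes without catching bare exceptions.
"""


class TrophicfluxError(Exception):
    """Base class for all trophicflux errors."""


class WebBuildError(TrophicfluxError):
    """Structurally invalid web input (duplicate ids, dangling links, ...)."""


class CycleError(TrophicfluxError):
    """The consumer-to-resource digraph contains a feeding loop.

    Carries the set of node ids that sit on at least one cycle.
    """

    def __init__(self, cycle_nodes, message=None):
        self.cycle_nodes = frozenset(cycle_nodes)
        if message is None:
            message = (
                "feeding loop among nodes {%s}; the sequential solver only "
                "handles acyclic webs — use solve_fluxes (matrix solver)"
                % ", ".join(sorted(self.cycle_nodes))
            )
        super().__init__(message)


class PreferenceError(TrophicfluxError):
    """A consumer's preference column cannot be normalized."""


class EfficiencyError(TrophicfluxError):
    """Assimilation efficiency missing or outside the (0, 1] proportion bound."""


class LossDerivationError(TrophicfluxError):
    """A consumer node has no route to a metabolic loss value."""


class InfeasibleFluxError(TrophicfluxError):
    """The energy balance has no nonnegative solution (or is singular)."""

    def __init__(self, message, offending_nodes=()):
        self.offending_nodes = tuple(offending_nodes)
        super().__init__(message)


class UnitsError(TrophicfluxError):
    """Incoherent or conflicting unit tags."""


class ConfigError(TrophicfluxError):
    """Invalid run configuration."""
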