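"""Exception hierarchy shared across the package."""


class CovpowerError(Exception):
    """Base class for all package errors."""


class FormatError(CovpowerError):
    """Malformed input file (Stockholm, FASTA, Newick, curve file)."""


class StructureError(CovpowerError):
    """Invalid or inconsistent secondary-structure annotation."""


class TreeError(CovpowerError):
    """Invalid tree or tree/alignment mismatch."""


class SimulationError(CovpowerError):
    """Simulation target unreachable or simulation precondition violated."""


class PowerError(CovpowerError):
    """Power-curve fitting or evaluation precondition violated."""
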