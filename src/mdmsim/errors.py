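"""Exception hierarchy for mdmsim."""


class MdmError(Exception):
    """Base class for all mdmsim errors."""


class LayoutError(MdmError):
    """A chip-layout document could not be parsed or is structurally invalid."""


class ProtocolParseError(MdmError):
    """A motion command or protocol script could not be parsed."""


class TransitionError(MdmError):
    """An illegal magnet/droplet transition was requested of the engine."""


class DegenerateReferenceError(MdmError):
    """Homogeneity is undefined because the two reference mixing indices coincide."""


class QuantificationError(MdmError):
    """Calibration, standard-curve fitting or LOD computation received invalid inputs."""
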