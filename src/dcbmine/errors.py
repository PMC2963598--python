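"""Exception hierarchy shared across the package."""


class DcbError(Exception):
    """Base class for all package errors."""


class UnknownGeneError(DcbError, KeyError):
    """A gene identifier is not part of the profile network."""

    def __init__(self, gene: str):
        super().__init__(gene)
        self.gene = gene

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"unknown gene identifier: {self.gene!r}"


class InputFormatError(DcbError, ValueError):
    """A file or record could not be parsed; message carries the location."""


class DomainError(DcbError, ValueError):
    """An argument is outside the documented domain of an operation."""


class SamplingError(DcbError, RuntimeError):
    """Random subnetwork sampling is infeasible on the given network."""


class StructureError(DcbError, ValueError):
    """An ontology edge table is not a rooted DAG."""


class PlantSpecError(DcbError, ValueError):
    """A synthetic-data specification is internally infeasible."""
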