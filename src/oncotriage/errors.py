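"""Exception hierarchy.

``DataError`` subclasses signal invalid input records or files and map to CLI
exit code 1; ``InvalidConfig`` signals an unusable policy or simulation
configuration.
"""


class OncoTriageError(Exception):
    """Base class for all package errors."""


class DataError(OncoTriageError):
    """Invalid input data (record-level or file-level)."""


class MissingSymptom(DataError):
    def __init__(self, symptom: str, checkin_id: str | None = None):
        self.symptom = symptom
        self.checkin_id = checkin_id
        where = f" in check-in {checkin_id!r}" if checkin_id else ""
        super().__init__(f"missing score for symptom {symptom!r}{where}")


class ScoreOutOfRange(DataError):
    def __init__(self, symptom: str, value, checkin_id: str | None = None):
        self.symptom = symptom
        self.value = value
        self.checkin_id = checkin_id
        where = f" in check-in {checkin_id!r}" if checkin_id else ""
        super().__init__(
            f"score {value!r} for symptom {symptom!r}{where} is not in 0..3"
        )


class BadTimestamp(DataError):
    def __init__(self, value, reason: str = "missing timezone offset or unparseable"):
        self.value = value
        super().__init__(f"bad timestamp {value!r}: {reason}")


class DuplicateCheckinId(DataError):
    def __init__(self, checkin_id: str):
        self.checkin_id = checkin_id
        super().__init__(f"duplicate check-in id {checkin_id!r}")


class UnknownSymptom(DataError):
    def __init__(self, name: str):
        self.name = name
        super().__init__(f"unknown symptom name {name!r}")


class MixedPatientEpisode(OncoTriageError):
    """Internal consistency failure: an episode mixing patients."""


class UnknownEpisodeReference(DataError):
    def __init__(self, episode_id: str):
        self.episode_id = episode_id
        super().__init__(f"review event references unknown episode {episode_id!r}")


class UnknownPatient(DataError):
    def __init__(self, patient_id: str):
        self.patient_id = patient_id
        super().__init__(f"no enrollment record for patient {patient_id!r}")


class EmptyInput(DataError):
    """An operation whose summary statistics are undefined on empty input."""


class ZeroExpectedDays(DataError):
    """Engagement denominator is zero."""


class EmptyRoster(DataError):
    """Per-patient burden summaries need a nonempty patient roster."""


class SchemaMismatch(DataError):
    def __init__(self, path, missing):
        self.path = str(path)
        self.missing = list(missing)
        super().__init__(f"{path}: missing required column(s) {sorted(self.missing)}")


class IOFailure(OncoTriageError):
    """Filesystem read/write failure."""


class InvalidConfig(OncoTriageError):
    """Policy or simulation configuration that fails validation."""
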