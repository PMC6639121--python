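"""Engine configuration: folder layout, worker pool, execution options."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class EngineConfig:
    """Folder contract and execution options for one engine instance.

    The four folders mirror the jobs/temp/output layout of a shared
    workflow-manager deployment: job files arrive in ``jobs_folder``,
    intermediate step data lives under ``temp_folder``, and results are
    delivered to each job's own output folder (``output_default`` backs
    jobs that give a relative path).  All folders are created on startup.
    """

    jobs_folder: Path = Path("jobs")
    temp_folder: Path = Path("temp")
    output_default: Path = Path("output")
    store_path: Path = Path("cwlflow.db")
    worker_count: int = 1
    poll_interval_s: float = 3.0
    retry_limit: int = 0
    container_mode: str = "none"          # none | docker | singularity
    keep_temp: bool = False
    log_level: str = "INFO"
    queue_names: set[str] = field(default_factory=lambda: {"default"})
    task_queue_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("jobs_folder", "temp_folder", "output_default", "store_path"):
            setattr(self, name, Path(getattr(self, name)))
        if self.worker_count < 1:
            raise ValueError("worker_count must be >= 1")
        if self.poll_interval_s <= 0:
            raise ValueError("poll_interval_s must be positive")
        if self.container_mode not in ("none", "docker", "singularity"):
            raise ValueError(f"unknown container_mode {self.container_mode!r}")
        bad = set(self.task_queue_assignment.values()) - self.queue_names
        if bad:
            raise ValueError(f"task queues {sorted(bad)} not in queue_names")

    def ensure_folders(self) -> None:
        for folder in (self.jobs_folder, self.temp_folder, self.output_default):
            folder.mkdir(parents=True, exist_ok=True)
        if not self.store_path.parent.exists():
            raise FileNotFoundError(
                f"store_path parent {self.store_path.parent} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "EngineConfig":
        """Load from a YAML mapping; keyword overrides win over the file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "queue_names" in data and not isinstance(data["queue_names"], set):
            data["queue_names"] = set(data["queue_names"])
        return cls(**data)
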