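/root/pkg/teststest_synthetic.pytest_boost.pytest_patterns.pytest_pipeline.pytest_acceptance.pytest_profiles.pytest_dags.pyconftest.pytest_votes.py     �   ����ar�B�2i����         �   ����K����zޅ���         �   �����Q��G�9����          �   g���y̯��.�c����         �   5�����oFz#����                                         �   ���������	�����          �   ������f6�0�����         �   �����Q����Յ���          �   W�����5y
������         	yC�yVwS	yC�yVwS����������� �   �������	   
   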