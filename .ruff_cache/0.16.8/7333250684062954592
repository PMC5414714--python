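/root/pkg/teststest_synthetic.pytest_boost.pytest_patterns.pytest_pipeline.pytest_acceptance.pytest_profiles.pytest_dags.pyconftest.pytest_votes.py     �   ����ar�B�2i�3���         �   �����m���Ý�3���         �   �����ך C�e��3���         �   g���y̯��.�c�3���         �   5�����oFz#��3���                                         �   �������*>r0�3���         �   ������f6�0��3���         �   �����ך C�e��3���         �   W�����5y
���3���         	yC�yVwS	yC�yVwS����������� �   �������	   
   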